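# Methods

## Image-formation model and conventions

All arrays are row-major with row = y (down) and col = x (right); lengths
are in nanometres, spatial frequencies in cycles/µm; spectra are stored
DC-centered with the DC element of an even N×N grid at index (N/2, N/2).
The frequency step per axis is 1/(N·Δx), so step × extent × pixel size = 1.

Raw frames follow the standard 2-D SIM mixing model: a cosine pattern
I₀[1 + m·cos(2π p_d·r + φ)] multiplies the fluorophore density, the product
is low-passed by the system OTF, a phase-independent defocus background is
added, and Gaussian noise is applied on the [0, 1]-normalized scale.
Pattern synthesis happens in real space (mathematically identical to the
frequency-domain statement of the model, but without wrap-around from
shifting truncated spectra).  Normalization to [0, 1] happens only when
noise is requested, so noiseless stacks keep exact linear identities —
this is what makes the separation and defocus-difference oracles in the
test suite exact to machine precision.

The OTF is the ideal incoherent transfer function of a circular pupil,
H(ρ̂) = (2/π)(arccos ρ̂ − ρ̂√(1−ρ̂²)) with ρ̂ = |k|/k_em and k_em = 2NA/λ_em.
A real microscope's OTF would be measured; the ideal form is closed-form
and exactly testable (H(0)=1, H(0.5)≈0.3910, H(1)=0).  Its PSF FWHM
(≈0.51·λ/NA; 178 nm at NA 1.5, λ 520 nm) is computed by numeric Hankel
integration and serves as the oracle for FWHM measurements.

### Defocus model

The out-of-focus contribution is modelled as an independent background
plane convolved with a wide Gaussian (default width 5× the in-focus PSF
FWHM) and scaled by a weight β (default 0.5), identical in all nine frames
— pattern contrast decays rapidly with defocus, so the out-of-focus plane
is effectively widefield-illuminated.  This is deliberately phenomenological:
it reproduces the defining property (a φ-independent additive field
confined to the order-0 band after separation) without a physical 3-D
defocus OTF, which is out of scope.

### Noise

Additive Gaussian noise with configurable mean and variance on the
normalized intensity scale, then clipping at 0 (camera floor).  The
defaults (mean 0.1, variance 0.1) reproduce the heavy-noise protocol used
for the resolution-board comparison; validation studies that need a
well-defined SNR use σ = signal RMS/10 (20 dB) with a +0.1 offset so the
camera floor does not rectify the noise.

## Band separation

Each orientation's three frames are un-mixed with the 3×3 matrix with rows
[1, (m/2)e^{−iφⱼ}, (m/2)e^{+iφⱼ}].  The (m/2) factors live in the matrix,
so the separated order-±1 bands carry C̃(k∓p)H̃(k) with no residual m
scaling.  The matrix is pixel-independent, so the solve is three weighted
frame sums with the explicit inverse.  For the nominal phases
{0, 2π/3, 4π/3} the columns are orthogonal with norms √3, √3/2, √3/2,
giving 2-norm condition number exactly 2.  Repeated phases (mod 2π) or
m = 0 raise a singular-matrix error.  Because the inverse's first row sums
to one while the other rows sum to zero, any frame-independent additive
field — the defocus background — lands entirely in the order-0 band; this
is the property the notch exploits downstream.

## Reconstruction

Bands are zero-pad-embedded into a 2× frequency grid (same frequency step,
doubled extent, half the pixel size), the order-±1 bands are translated to
±p_d by sub-pixel Fourier shifts (real-space phase ramp; exact for the
periodic discrete signal and identical to an array roll for integer
shifts), and the shifted OTF copies are evaluated analytically at
H(|k∓p_d|).  The default combination pools one Wiener denominator over
all bands,

    g(r) = ifft[ (F·Σ_d H̃₀S₀d + Σ_{n=±1,d} H̃_{nd}S_{nd}) / (Σ_all H̃² + α²) · A(k̃) ],

with the notch F multiplying only the order-0 numerator term.  A two-term
form with separate order-0/order-±1 denominators is available
(`pool_denominator=False`); it is not the default because the two terms
each reach unit response over the band-overlap region, double-counting
low frequencies and measurably broadening the PSF (widefield/SR FWHM
ratio 1.54–1.66 instead of ≈1.9 on the bead benchmark).  With the notch
disabled both paths are bit-identical to the plain Wiener reconstruction
by construction (same code path, F ≡ 1).

Parameter choices:

* **α (Wiener regularizer)** — 0.1 on the OTF-normalized scale.  A scale-free
  trade-off between noise amplification and band-edge roll-off; exposed as
  a flag.
* **σ (notch width)** — 2 frequency pixels of the raw grid.  The raw and
  upsampled grids share one frequency step, so the value carries over
  unchanged.  Small σ notches only the immediate DC neighbourhood (the
  defocus haze and the noise-mean offset); large σ starts eating genuine
  sample structure.  The σ sweep in the CLI tabulates this trade-off.
* **A(k̃) (apodization)** — triangle to the extended cutoff k_em + max|p_d|
  (default), a stretched ideal-OTF shape, or none.  The taper suppresses
  ringing at the hard support edge.
* **Output** — real part of the inverse transform at 2× sampling, stored
  unclipped; a clipped copy is available for display.

## Illumination-parameter estimation

* **Wave vector.**  The order-0 and order-+1 bands (separated with nominal
  phases and unit carrier coefficients) are cross-correlated over relative
  frequency shifts after normalizing every spectral sample to unit
  magnitude.  This phase-only (whitened) correlation removes the sample's
  colored spectrum and the OTF envelope, so the only coherent alignment is
  the fringe shift p.  The coarse integer peak is searched on
  Tukey-windowed frames (windowing suppresses field-of-view leakage
  streaks) inside the annulus 0.5–1.02 k_em, where SIM pattern frequencies
  live and where the clipping residue around DC cannot intrude; a
  fringe-free stack fails a random-phasor-walk noise gate.  Sub-pixel
  refinement evaluates the correlation on zoomed DFT grids (three stages,
  final step 2·10⁻⁴ px) on the unwindowed bands.  The order-−1 band is the
  conjugate mirror of the order-+1 band for real frames and adds no
  information.  The estimate is canonicalized to the upper half-plane
  (a cosine fringe is invariant under (p, φ) → (−p, −φ)).
* **Phases.**  Phase-of-peak: the argument of each raw-frame spectrum at
  the sub-pixel location p̂, evaluated by a direct DFT on edge-windowed
  frames.  The object's own spectral content at p̂ adds one common complex
  offset to the three peak values; under the 2π/3 protocol the fringe
  terms sum to zero over the frames, so subtracting the complex mean
  removes that leakage exactly.  Note the identifiability caveat: a
  corner-referenced absolute phase is amplified by wave-vector error times
  half the field size; the physically meaningful quantity is the fringe
  phase at the field centre, and accuracy statements are made there.
* **Modulation depth.**  Least-squares amplitude ratio of the order-±1
  bands to the sub-pixel-shifted order-0 band over the OTF overlap
  (support floor H > 0.05), m̂ = 2·|ratio|.  Two numerical safeguards: a
  smooth DC notch is applied to the order-0 band before shifting (its DC
  cone rings under trigonometric interpolation), and the regression treats
  the interpolation-free order-±1 side as the regressor, avoiding the
  errors-in-variables attenuation (5–11% low otherwise).

## Evaluation and quantification

PSNR is 10·log₁₀(peak²/MSE) with an infinite-value sentinel for identical
images; SSIM is the standard 11-sample Gaussian-window form
(scikit-image's implementation with σ = 1.5 and population covariances);
profiles are bilinear; FWHM comes from a least-squares Gaussian fit with
baseline (FWHM = 2√(2 ln 2)·σ); background statistics use the population
standard deviation.  Object counting contrast-stretches, thresholds (Otsu
or fixed), prunes components below 9 px, and labels 8-connected components;
droplet detection runs a Canny edge map through a circular Hough transform,
with each radius refined by the accumulator centroid across the radius axis
(the edge map votes on both sides of a soft ring; the centroid recovers the
ridge).  Histogram bins are half-open, right-open.

## What the synthetic data does and does not emulate

Phantoms (sub-pixel point beads, bar-triplet resolution board, random
filaments, droplet rings/disks, smooth blob fields) are rendered on the 2×
super-resolution grid; the simulator input is the 2×2 block mean, and the
fine render doubles as the ground truth for PSNR/SSIM.  The simulation is
periodic and Gaussian-noise only: it omits Poisson statistics, spectrally
varying camera noise, aberrated/measured OTFs, pattern distortion across
the field, photobleaching and sample motion.  Passing tests therefore
demonstrate correctness of the algorithmic chain under its stated model,
not robustness to every real-microscope nuisance; the estimator and the
notch operate on raw frames alone, so they apply to real data unchanged,
but their quantitative error bounds are statements about this simulator.

## Validation-study problem sizes

Chosen so every study runs in seconds on one CPU while staying in the
regime where the measured quantities are stable: bead/board benchmarks on
256² raw grids (512² reconstructions), defocus-suppression runs on 192²
(10 runs), parameter recovery on 256² over 20 random draws (on smaller
fields the whitened correlation's random-walk floor, ~√N_support/N_overlap
frequency pixels, approaches the accuracy being measured), droplet panels
on 768² with 50 rings of 300–900 nm radius and ≥2-radius separation.  The
defocus background fluctuation is measured over the structure-free margin
band of the reconstruction (several µm long): the out-of-focus field
varies on the ~0.5–1 µm blur scale, so a region must span several such
patches for its standard deviation to characterize the fluctuation.

## Known limitations

2-D (single-slice) SIM only; exactly three orientations × three phases;
no measured-OTF input; no Richardson–Lucy or iterative-deconvolution
comparison path; the modulation-depth estimate degrades near the cutoff
(|p| > 0.95 k_em) where the band overlap thins; absolute fringe phases
are reported in the corner-origin convention and inherit wave-vector
uncertainty away from the field centre.
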