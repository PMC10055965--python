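# notchsim

Structured-illumination microscopy (SIM) reconstruction with a
notch-filtered low-frequency band for suppressing the streak artifacts
that out-of-focus fluorescence causes in thick samples — together with a
forward simulator, illumination-parameter estimation, image-quality
metrics, and organelle quantification, so the whole method can be
validated end to end on synthetic data with known ground truth.

## Who this is for

SIM practitioners and method developers who want a small, fully inspectable
2-D SIM reconstruction pipeline whose every stage — image formation, band
separation, Wiener combination, notch filtering — is testable against
analytic oracles, and who need a defocus-robust reconstruction for samples
(e.g. live hepatocytes) too thick for TIRF-style optical sectioning.

## The model

A cosine illumination pattern with wave vector **p**_d, phase φ and
modulation depth m mixes the sample spectrum C̃(k) into each raw frame:

    Ẽ_{d,φ}(k) = I₀ [ C̃(k) + (m/2) C̃(k+p_d) e^{−iφ} + (m/2) C̃(k−p_d) e^{+iφ} ] H̃(k) + D̃_bg(k)

where H̃(k) is the system OTF with cutoff k_em = 2NA/λ_em and D̃_bg is the
out-of-focus background.  Three phases per orientation (step 2π/3) give a
3×3 linear system whose inversion separates the order-0 band S₀ = C̃H̃ and
the order-±1 bands C̃(k±p)H̃.  Because the defocus background is the same
in all three frames, it lands entirely in S₀.

The generalized Wiener reconstruction combines all shifted bands:

    g(r) = ifft [ Σ_{n,d} H̃*_{nd}(k+np_d) S_{nd}(k+np_d) / (Σ |H̃|² + α²) · A(k̃) ]

The notched variant (N-SIM) multiplies the order-0 term by a notch filter

    F(k) = 1 − exp(−r²/(2σ²)),   F(0) = 0,  F → 1 at high frequency,

which removes the defocus-contaminated low frequencies while the order-±1
bands re-supply the genuine low-frequency information of the sample.  With
the notch disabled the two paths are bit-identical.

## Worked example

Simulate a defocus-contaminated 9-frame acquisition of a filament phantom,
reconstruct with and without the notch (illumination parameters estimated
from the data), and compare against the ground truth:

```bash
cat > sim.yaml <<EOF
seed: 7
phantom: {kind: filaments, shape: [192, 192], params: {n: 8, margin: 40}}
optical: {emission_wavelength_nm: 520, numerical_aperture: 1.5, pixel_size_nm: 40}
illumination: {freq_fraction: 0.9, modulation: 0.9}
defocus: {enabled: true, amplitude: 0.5}
noise: {enabled: true, mean: 0.05, variance: 0.0001}
EOF
notchsim simulate -c sim.yaml -o stack.tif
notchsim reconstruct stack.tif --method nsim   -o sr_nsim.tif
notchsim reconstruct stack.tif --method wiener -o sr_wiener.tif
notchsim evaluate sr_nsim.tif   --truth stack_truth.tif --background-box 8,8,40,376 -o metrics_nsim.csv
notchsim evaluate sr_wiener.tif --truth stack_truth.tif --background-box 8,8,40,376 -o metrics_wiener.csv
```

The metric tables this prints:

| metric           | N-SIM  | Wiener |
|------------------|-------:|-------:|
| psnr_db          | 29.76  | 23.94  |
| ssim             | 0.888  | 0.068  |
| background_mean  | −0.001 | 0.116  |
| background_std   | 0.134  | 0.141  |

The notch removes the out-of-focus haze: the background region drops to
zero mean with lower fluctuation, and fidelity to the in-focus ground truth
improves by almost 6 dB.  `notchsim sweep-sigma` tabulates the same metrics
over a ladder of notch widths σ (σ = 2 frequency pixels is the default:
strong background suppression with weak in-focus detail retained), and
`notchsim quantify` counts mitochondria-like objects over time or detects
lipid-droplet circles with a radius histogram.

The same pipeline is available as a library:

```python
import notchsim as ns

stack = ns.read_stack_tiff("stack.tif")
sr = ns.reconstruct(stack, method="nsim")   # parameters estimated from the data
```

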