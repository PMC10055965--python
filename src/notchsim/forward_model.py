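"""Synthetic SIM image formation: phantoms, OTF, cosine illumination,
defocus background, and noise.

The raw-frame model is, in the frequency domain,

    Ẽ_{d,φ}(k) = I0·[C̃(k) + (m/2)C̃(k+p_d)e^{-iφ} + (m/2)C̃(k−p_d)e^{+iφ}]·H̃(k)
                 + D̃bg(k)

with C̃ the in-focus sample spectrum, H̃ the system OTF with cutoff
kem = 2NA/λem, p_d the illumination wave vector of orientation d, m the
modulation depth, and D̃bg a phase-independent out-of-focus background.
Frames are synthesized in real space as
``(sample · I0·[1 + m·cos(2π p_d·r + φ)]) ⊗ PSF + β·(background ⊗ wide blur)``,
which is the same model without explicit spectral shifting (and hence
without wrap-around from shifting truncated spectra).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage

from .core import NM_PER_UM, FrequencyGrid, OpticalParams, RawSIMStack

__all__ = [
    "SampleImage",
    "OTFModel",
    "IlluminationParams",
    "DefocusConfig",
    "NoiseConfig",
    "make_otf",
    "make_phantom",
    "simulate_raw_stack",
    "psf_fwhm_nm",
    "downsample2",
]


@dataclass
class SampleImage:
    """Fluorophore density map on a uniform grid (arbitrary units, ≥ 0)."""

    density: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if not np.all(np.isfinite(self.density)):
            raise ValueError("sample density must be finite")
        if np.any(self.density < 0):
            raise ValueError("sample density must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape


@dataclass
class OTFModel:
    """System OTF H̃(k) sampled on a DC-centered frequency grid."""

    values: np.ndarray
    cutoff: float
    grid: FrequencyGrid
    optical: OpticalParams | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("OTF values must match the frequency grid")

    def shifted(self, center: tuple[float, float], grid: FrequencyGrid | None = None) -> np.ndarray:
        """H̃ evaluated with its support centered at a frequency point.

        ``center`` is (qx, qy) in cycles/µm; the returned array lives on
        ``grid`` (default: the model's own grid).
        """
        g = self.grid if grid is None else grid
        return otf_radial(g.radial_distance_from(center), self.cutoff)


def otf_radial(k: np.ndarray, cutoff: float) -> np.ndarray:
    """Ideal incoherent OTF of a circular pupil as a function of |k|.

    H(ρ̂) = (2/π)(arccos ρ̂ − ρ̂·sqrt(1 − ρ̂²)) for ρ̂ = |k|/cutoff ≤ 1, else 0.
    """
    rho = np.clip(np.abs(k) / cutoff, 0.0, 1.0)
    h = (2.0 / np.pi) * (np.arccos(rho) - rho * np.sqrt(1.0 - rho * rho))
    h[np.abs(k) >= cutoff] = 0.0
    return h


def make_otf(optical: OpticalParams, grid: FrequencyGrid) -> OTFModel:
    """Ideal incoherent circular-pupil OTF for the given optics on `grid`."""
    if grid.shape != tuple(optical.image_shape):
        raise ValueError("grid shape disagrees with optical.image_shape")
    cutoff = optical.cutoff
    nyquist = 0.5 / (grid.pixel_size_nm / NM_PER_UM)
    if cutoff > nyquist:
        import warnings

        warnings.warn(
            f"OTF cutoff {cutoff:.3g} cycles/um exceeds the grid Nyquist "
            f"{nyquist:.3g}; the OTF is truncated by sampling",
            stacklevel=2,
        )
    return OTFModel(
        values=otf_radial(grid.radial_magnitude, cutoff),
        cutoff=cutoff,
        grid=grid,
        optical=optical,
    )


def psf_fwhm_nm(optical: OpticalParams) -> float:
    """FWHM of the in-focus PSF (transform of the ideal OTF), in nm.

    Computed numerically from the radially symmetric PSF profile; for the
    circular-pupil OTF this is ≈ 0.51·λem/NA.
    """
    # dense 1-D Hankel-style evaluation: PSF(r) ∝ ∫ H(k) J0(2π k r) k dk
    from scipy.special import j0

    kem = optical.cutoff
    k = np.linspace(0.0, kem, 2048)
    h = otf_radial(k, kem)
    r_um = np.linspace(0.0, 2.0 * optical.emission_wavelength_nm / NM_PER_UM, 4096)
    psf = np.array([np.trapezoid(h * j0(2 * np.pi * k * r) * k, k) for r in r_um])
    psf /= psf[0]
    half = np.nonzero(psf < 0.5)[0][0]
    # linear interpolation across the half crossing
    r0, r1 = r_um[half - 1], r_um[half]
    p0, p1 = psf[half - 1], psf[half]
    r_half = r0 + (0.5 - p0) * (r1 - r0) / (p1 - p0)
    return 2.0 * r_half * NM_PER_UM


@dataclass
class IlluminationParams:
    """Cosine illumination pattern parameters for the 3×3 acquisition.

    ``wave_vectors`` has shape (3, 2) holding (px, py) per orientation in
    cycles/µm; ``phases`` has shape (3, 3): the three pattern phases per
    orientation (nominal step 2π/3).
    """

    wave_vectors: np.ndarray
    phases: np.ndarray
    modulation: float = 0.9
    intensity: float = 1.0

    def __post_init__(self) -> None:
        self.wave_vectors = np.asarray(self.wave_vectors, dtype=np.float64).reshape(3, 2)
        self.phases = np.asarray(self.phases, dtype=np.float64).reshape(3, 3)
        if not (0.0 <= self.modulation <= 1.0):
            raise ValueError("modulation depth must lie in [0, 1]")
        if self.intensity <= 0:
            raise ValueError("illumination intensity must be positive")

    @classmethod
    def nominal(
        cls,
        optical: OpticalParams,
        freq_fraction: float = 0.9,
        angles_deg: tuple[float, float, float] = (0.0, 60.0, 120.0),
        modulation: float = 0.9,
        phase0: float = 0.0,
        intensity: float = 1.0,
    ) -> "IlluminationParams":
        """Standard acquisition: |p| = freq_fraction·kem at three angles,
        phases stepped by 2π/3 in every orientation."""
        mag = freq_fraction * optical.cutoff
        ang = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
        wave_vectors = mag * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        phases = phase0 + np.tile(np.arange(3) * 2 * np.pi / 3, (3, 1))
        return cls(wave_vectors=wave_vectors, phases=phases, modulation=modulation, intensity=intensity)

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.rad2deg(np.arctan2(self.wave_vectors[:, 1], self.wave_vectors[:, 0]))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.wave_vectors[:, 0], self.wave_vectors[:, 1])


@dataclass
class DefocusConfig:
    """Out-of-focus background: a second sample plane seen through a wide blur.

    ``blur_sigma_nm`` is the Gaussian blur width (must exceed the in-focus
    PSF width); ``amplitude`` is the weight β of the background relative to
    the in-focus signal.  The background is identical in all nine frames
    (the fringe contrast of the out-of-focus plane is negligible).
    """

    background_sample: SampleImage
    blur_sigma_nm: float
    amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("defocus amplitude must be non-negative")
        if self.blur_sigma_nm <= 0:
            raise ValueError("defocus blur width must be positive")

    def background_field(self, optical: OpticalParams) -> np.ndarray:
        """β·(background ⊗ Gaussian blur) on the raw grid."""
        fwhm = psf_fwhm_nm(optical)
        if self.blur_sigma_nm <= fwhm / 2.3548:
            raise ValueError(
                "defocus blur width must exceed the in-focus PSF width "
                f"({fwhm / 2.3548:.1f} nm sigma)"
            )
        sigma_px = self.blur_sigma_nm / self.background_sample.pixel_size_nm
        blurred = ndimage.gaussian_filter(self.background_sample.density, sigma_px, mode="wrap")
        return self.amplitude * blurred


@dataclass
class NoiseConfig:
    """Additive Gaussian noise on the [0, 1]-normalized intensity scale."""

    gaussian_mean: float = 0.1
    gaussian_variance: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_variance < 0:
            raise ValueError("noise variance must be non-negative")


# --------------------------------------------------------------------------
# Phantoms


def make_phantom(
    kind: str,
    shape: tuple[int, int] = (256, 256),
    params: dict[str, Any] | None = None,
    seed: int = 0,
    pixel_size_nm: float = 40.0,
) -> tuple[SampleImage, dict]:
    """Generate a test phantom with its ground truth.

    Kinds
    -----
    ``beads``
        ``n`` sub-pixel point emitters (bilinear splat); truth lists their
        (x, y) coordinates in nm.  ``positions`` may pin them explicitly
        (list of (x, y) nm); ``margin`` keeps random beads away from the
        border (pixels).
    ``resolution_board``
        Bar-triplet groups of decreasing pitch; truth lists the pitches (nm).
    ``filaments``
        Random smooth curved filaments; truth records the waypoint tracks.
        ``margin`` keeps them away from the border.
    ``droplets``
        Rings (annuli) of given ``radii_nm``; truth is a table of centers
        (nm) and radii (nm).  ``filled=True`` draws disks instead.

    Returns (SampleImage, ground_truth_dict).  Deterministic in ``seed``.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 64 or cols < 64:
        raise ValueError("phantom shape must be at least 64×64")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    img = np.zeros((rows, cols), dtype=np.float64)

    if kind == "beads":
        n = int(params.get("n", 30))
        margin = float(params.get("margin", 8))
        amplitude = float(params.get("amplitude", 1.0))
        positions = params.get("positions")
        if positions is not None:
            pos_px = np.asarray(positions, dtype=np.float64) / pixel_size_nm
        else:
            pos_px = np.column_stack(
                [
                    rng.uniform(margin, cols - 1 - margin, n),
                    rng.uniform(margin, rows - 1 - margin, n),
                ]
            )
        for x, y in pos_px:
            _splat_bilinear(img, x, y, amplitude)
        truth = {
            "kind": "beads",
            "positions_nm": pos_px * pixel_size_nm,
        }
    elif kind == "resolution_board":
        pitches_px = params.get("pitches_px", [16, 12, 8, 6, 4, 3])
        bar_len = rows // 8
        y0 = rows // 8
        x = cols // 10
        pitches_nm = []
        for pitch in pitches_px:
            pitch = int(pitch)
            width = max(1, pitch // 2)
            for b in range(3):
                x_bar = x + b * pitch
                img[y0 : y0 + bar_len, x_bar : x_bar + width] = 1.0
                img[y0 + bar_len + pitch : y0 + bar_len + pitch + width, x : x + 3 * pitch] = 1.0
            pitches_nm.append(pitch * pixel_size_nm)
            x += 3 * pitch + max(4, pitch)
            if x > cols - 3 * pitch - 4:
                x = cols // 10
                y0 += bar_len + 6 * max(pitches_px) // 2
        truth = {"kind": "resolution_board", "pitches_nm": np.asarray(pitches_nm)}
    elif kind == "filaments":
        n = int(params.get("n", 6))
        margin = float(params.get("margin", 10))
        tracks = []
        for _ in range(n):
            length = int(rng.integers(rows // 2, rows))
            x = rng.uniform(margin, cols - 1 - margin)
            y = rng.uniform(margin, rows - 1 - margin)
            theta = rng.uniform(0, 2 * np.pi)
            pts = []
            for _ in range(length):
                theta += rng.normal(0.0, 0.15)
                x = np.clip(x + np.cos(theta), margin, cols - 1 - margin)
                y = np.clip(y + np.sin(theta), margin, rows - 1 - margin)
                _splat_bilinear(img, x, y, 1.0)
                pts.append((x, y))
            tracks.append(np.asarray(pts) * pixel_size_nm)
        img = ndimage.gaussian_filter(img, 0.7)
        truth = {"kind": "filaments", "tracks_nm": tracks}
    elif kind == "droplets":
        radii_nm = params.get("radii_nm")
        n = int(params.get("n", 6 if radii_nm is None else len(radii_nm)))
        margin_extra = float(params.get("margin", 4))
        filled = bool(params.get("filled", False))
        thickness = float(params.get("thickness_px", 1.5))
        min_sep_factor = float(params.get("min_separation_factor", 2.0))
        if radii_nm is None:
            # lipid-droplet scale; sorted large-first so placement packs
            radii_nm = np.sort(rng.uniform(300.0, 700.0, n))[::-1]
        radii_nm = np.asarray(radii_nm, dtype=np.float64)
        radii_px = radii_nm / pixel_size_nm
        centers = _place_non_overlapping(
            rng, rows, cols, radii_px, margin_extra, min_sep_factor
        )
        yy, xx = np.mgrid[0:rows, 0:cols]
        for (cy, cx), r_px in zip(centers, radii_px):
            d = np.hypot(xx - cx, yy - cy)
            if filled:
                img += np.clip(r_px + 0.5 - d, 0.0, 1.0)
            else:
                img += np.exp(-((d - r_px) ** 2) / (2.0 * (thickness / 2.3548) ** 2))
        img = np.clip(img, 0.0, None)
        truth = {
            "kind": "droplets",
            "centers_nm": np.asarray([(cx * pixel_size_nm, cy * pixel_size_nm) for cy, cx in centers]),
            "radii_nm": radii_nm,
        }
    elif kind == "blobs":
        # smooth random field; used as an out-of-focus background plane
        n = int(params.get("n", 40))
        sigma_px = float(params.get("sigma_px", 6.0))
        amp = rng.uniform(0.5, 1.5, n)
        xs = rng.uniform(0, cols - 1, n)
        ys = rng.uniform(0, rows - 1, n)
        for a, x, y in zip(amp, xs, ys):
            _splat_bilinear(img, x, y, a)
        img = ndimage.gaussian_filter(img, sigma_px, mode="wrap")
        img /= img.max() if img.max() > 0 else 1.0
        truth = {"kind": "blobs"}
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")

    return SampleImage(density=img, pixel_size_nm=pixel_size_nm), truth


def _splat_bilinear(img: np.ndarray, x: float, y: float, amplitude: float) -> None:
    """Deposit a sub-pixel point source onto the 4 neighbouring pixels."""
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < img.shape[0] and 0 <= xx < img.shape[1]:
                img[yy, xx] += amplitude * wy * wx


def _place_non_overlapping(rng, rows, cols, radii_px, margin_extra, min_sep_factor, max_tries=20000):
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii_px:
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r + margin_extra, rows - 1 - r - margin_extra)
            cx = rng.uniform(r + margin_extra, cols - 1 - r - margin_extra)
            if all(
                np.hypot(cy - oy, cx - ox) >= min_sep_factor * max(r, orr)
                for (oy, ox), orr in zip(centers, placed_r)
            ):
                centers.append((cy, cx))
                placed_r.append(r)
                ok = True
                break
        if not ok:
            raise ValueError("could not place droplets without overlap; reduce n or radii")
    return centers


def downsample2(image: np.ndarray) -> np.ndarray:
    """2×2 block-mean downsample (fine-grid phantom → raw-grid sample)."""
    rows, cols = image.shape
    if rows % 2 or cols % 2:
        raise ValueError("shape must be even for 2× downsampling")
    return image.reshape(rows // 2, 2, cols // 2, 2).mean(axis=(1, 3))


# --------------------------------------------------------------------------
# Raw-stack synthesis


def simulate_raw_stack(
    sample: SampleImage,
    illum: IlluminationParams,
    otf: OTFModel,
    defocus: DefocusConfig | None = None,
    noise: NoiseConfig | None = None,
) -> RawSIMStack:
    """Render the 9 raw frames of a SIM acquisition.

    Noiseless frames follow the image-formation model exactly; with a
    ``NoiseConfig`` the stack is first normalized to [0, 1] by its global
    maximum, then Gaussian noise is added and negatives are clipped to 0.
    """
    rows, cols = sample.shape
    if otf.grid.shape != (rows, cols):
        raise ValueError("OTF grid does not match the sample shape")
    if np.any(illum.magnitude() > otf.cutoff * (1 + 1e-9)):
        raise ValueError("illumination wave vector exceeds the OTF cutoff kem")
    optical = otf.optical if otf.optical is not None else _optics_like(sample, otf)
    if tuple(optical.image_shape) != (rows, cols) or optical.pixel_size_nm != sample.pixel_size_nm:
        optical = OpticalParams(
            emission_wavelength_nm=optical.emission_wavelength_nm,
            numerical_aperture=optical.numerical_aperture,
            pixel_size_nm=sample.pixel_size_nm,
            image_shape=(rows, cols),
        )

    # Real-space coordinates in µm for the pattern phase
    x_um = np.arange(cols) * sample.pixel_size_nm / NM_PER_UM
    y_um = np.arange(rows) * sample.pixel_size_nm / NM_PER_UM
    xx, yy = np.meshgrid(x_um, y_um)

    h_unshifted = np.fft.ifftshift(otf.values)
    frames = np.empty((3, 3, rows, cols), dtype=np.float64)
    for d in range(3):
        px, py = illum.wave_vectors[d]
        carrier = 2 * np.pi * (px * xx + py * yy)
        for j in range(3):
            pattern = illum.intensity * (
                1.0 + illum.modulation * np.cos(carrier + illum.phases[d, j])
            )
            blurred = np.fft.ifft2(np.fft.fft2(sample.density * pattern) * h_unshifted).real
            frames[d, j] = blurred

    if defocus is not None:
        frames += defocus.background_field(optical)

    if noise is not None:
        peak = frames.max()
        if peak > 0:
            frames = frames / peak
        rng = np.random.default_rng(noise.seed)
        frames = frames + noise.gaussian_mean + np.sqrt(noise.gaussian_variance) * rng.standard_normal(
            frames.shape
        )

    frames = np.clip(frames, 0.0, None)
    return RawSIMStack(
        frames=frames,
        orientations_deg=illum.orientations_deg,
        nominal_phases_rad=illum.phases[0] % (2 * np.pi),
        optical=optical,
    )


def _optics_like(sample: SampleImage, otf: OTFModel) -> OpticalParams:
    """Reconstruct OpticalParams consistent with the OTF cutoff.

    The cutoff fixes only the ratio NA/λ; NA is reported as 1.0 with the
    wavelength chosen to match, which leaves every downstream computation
    (all keyed on the cutoff) unchanged.
    """
    return OpticalParams(
        emission_wavelength_nm=2.0 / otf.cutoff * NM_PER_UM,
        numerical_aperture=1.0,
        pixel_size_nm=sample.pixel_size_nm,
        image_shape=sample.shape,
    )
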