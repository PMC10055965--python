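"""Image-quality measurements: PSNR, SSIM, line profiles, FWHM, and
background-region statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.metrics import structural_similarity

__all__ = [
    "LineProfile",
    "FWHMResult",
    "psnr",
    "ssim",
    "line_profile",
    "fwhm",
    "background_stats",
]


class FitError(RuntimeError):
    """Raised when a profile fit cannot be performed."""


@dataclass
class LineProfile:
    """Intensities sampled along a segment; positions in nm."""

    positions_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions_nm.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions_nm.size >= 2 and not np.all(np.diff(self.positions_nm) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class FWHMResult:
    """Gaussian-fit peak description of a line profile."""

    center_nm: float
    width_nm: float  # Gaussian sigma
    fwhm_nm: float
    residual: float


def psnr(reference: np.ndarray, test: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio, 10·log10(peak² / MSE), in dB.

    ``peak`` defaults to the reference maximum.  Identical images return
    ``inf`` rather than raising.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("images must share one shape")
    if peak is None:
        peak = float(reference.max())
    if peak <= 0:
        raise ValueError("peak intensity must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float | None = None) -> float:
    """Mean structural similarity with the standard 11-sample Gaussian
    window (σ = 1.5) and stabilizing constants from the dynamic range."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("images must share one shape")
    if data_range is None:
        data_range = float(reference.max() - reference.min())
        if data_range == 0:
            data_range = 1.0
    return float(
        structural_similarity(
            reference,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def line_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
    pixel_size_nm: float = 1.0,
) -> LineProfile:
    """Bilinear interpolation along the segment p0 → p1.

    Endpoints are (x, y) in pixel coordinates; positions are reported in
    nm measured from p0.
    """
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    for x, y in (p0, p1):
        if not (0 <= x <= cols - 1 and 0 <= y <= rows - 1):
            raise ValueError("profile endpoints must lie inside the image")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    values = ndimage.map_coordinates(image, np.vstack([ys, xs]), order=1, mode="nearest")
    length_nm = np.hypot(p1[0] - p0[0], p1[1] - p0[1]) * pixel_size_nm
    return LineProfile(positions_nm=t * length_nm, intensities=values)


def _gaussian(x, amplitude, center, sigma, baseline):
    return baseline + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fwhm(profile: LineProfile) -> FWHMResult:
    """Least-squares Gaussian fit of a single-peak profile.

    FWHM = 2·sqrt(2·ln 2)·σ ≈ 2.3548·σ.  Raises ``FitError`` for flat or
    peak-free profiles.
    """
    x = profile.positions_nm
    y = profile.intensities
    if x.size < 5:
        raise FitError("profile too short for a Gaussian fit")
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-12 * max(1.0, abs(float(y.max()))):
        raise FitError("flat profile: no peak to fit")
    i_max = int(np.argmax(y))
    guess = (span, float(x[i_max]), float((x[-1] - x[0]) / 10.0), float(y.min()))
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            x,
            y,
            p0=guess,
            bounds=(
                [0.0, x[0], (x[1] - x[0]) / 10.0, -np.inf],
                [np.inf, x[-1], (x[-1] - x[0]), np.inf],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit failed: {exc}") from exc
    amplitude, center, sigma, baseline = popt
    if amplitude <= 0 or not np.isfinite(sigma):
        raise FitError("no positive peak found")
    residual = float(np.sqrt(np.mean((_gaussian(x, *popt) - y) ** 2)))
    return FWHMResult(
        center_nm=float(center),
        width_nm=float(sigma),
        fwhm_nm=float(2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma),
        residual=residual,
    )


def background_stats(image: np.ndarray, region: np.ndarray | tuple) -> dict:
    """Descriptive statistics over a region (boolean mask or slice box).

    ``region`` may be a boolean mask of the image shape or a
    ``(row0, col0, row1, col1)`` box.  Standard deviation uses the
    population convention (divide by N).
    """
    image = np.asarray(image, dtype=np.float64)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != image.shape:
            raise ValueError("mask must match the image shape")
        values = image[region]
    else:
        r0, c0, r1, c1 = (int(v) for v in region)
        values = image[r0:r1, c0:c1].ravel()
    if values.size == 0:
        raise ValueError("region is empty")
    return {
        "mean": float(values.mean()),
        "std": float(values.std()),
        "range": float(values.max() - values.min()),
        "n": int(values.size),
    }
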