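"""Shared domain types, frequency-grid construction, and TIFF stack I/O.

Conventions used throughout the package:

* arrays are row-major; ``row`` is y (increasing downward), ``col`` is x
  (increasing rightward);
* lengths are in nanometres, spatial frequencies in cycles per micrometre;
* all spectra are stored DC-centered; the DC element of an even-sized
  ``N x N`` grid sits at index ``(N//2, N//2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "OpticalParams",
    "FrequencyGrid",
    "RawSIMStack",
    "SRImage",
    "make_frequency_grid",
    "read_stack_tiff",
    "write_stack_tiff",
]

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class OpticalParams:
    """Physical parameters of the widefield detection path.

    Attributes
    ----------
    emission_wavelength_nm : float
        Fluorescence emission wavelength λem, nm.
    numerical_aperture : float
        Objective NA (0 < NA <= 1.7).
    pixel_size_nm : float
        Sample-plane pixel size of the raw camera frames, nm.
    image_shape : tuple of int
        (rows, cols) of the raw frames.
    """

    emission_wavelength_nm: float
    numerical_aperture: float
    pixel_size_nm: float
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.emission_wavelength_nm <= 0:
            raise ValueError("emission wavelength must be positive")
        if not (0 < self.numerical_aperture <= 1.7):
            raise ValueError("numerical aperture must lie in (0, 1.7]")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image shape must be positive")
        object.__setattr__(self, "image_shape", (int(rows), int(cols)))

    @property
    def cutoff(self) -> float:
        """Incoherent OTF cutoff kem = 2 NA / λem, cycles/µm."""
        return 2.0 * self.numerical_aperture / (self.emission_wavelength_nm / NM_PER_UM)


@dataclass(frozen=True)
class FrequencyGrid:
    """DC-centered spatial-frequency grid for an image of a given shape.

    ``kx``/``ky`` are the per-pixel frequency coordinates (cycles/µm);
    ``radial_magnitude`` is |k|.  ``spacing`` is the frequency step per
    axis, 1/(N·Δx).
    """

    shape: tuple[int, int]
    spacing: tuple[float, float]
    kx: np.ndarray
    ky: np.ndarray
    radial_magnitude: np.ndarray
    pixel_size_nm: float

    @property
    def center(self) -> tuple[int, int]:
        return self.shape[0] // 2, self.shape[1] // 2

    def radial_distance_from(self, point: Sequence[float]) -> np.ndarray:
        """|k - q| for a frequency-space point q = (qx, qy) in cycles/µm."""
        qx, qy = point
        return np.hypot(self.kx - qx, self.ky - qy)


def make_frequency_grid(shape: tuple[int, int], pixel_size_nm: float) -> FrequencyGrid:
    """Build the DC-centered frequency grid for an image shape.

    Parameters
    ----------
    shape : (rows, cols)
        Image shape; each axis must be at least 8 samples.
    pixel_size_nm : float
        Real-space sampling step, nm.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 8 or cols < 8:
        raise ValueError("grid axes must have at least 8 samples")
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    dx_um = pixel_size_nm / NM_PER_UM
    fy = np.fft.fftshift(np.fft.fftfreq(rows, d=dx_um))
    fx = np.fft.fftshift(np.fft.fftfreq(cols, d=dx_um))
    kx, ky = np.meshgrid(fx, fy)
    return FrequencyGrid(
        shape=(rows, cols),
        spacing=(1.0 / (rows * dx_um), 1.0 / (cols * dx_um)),
        kx=kx,
        ky=ky,
        radial_magnitude=np.hypot(kx, ky),
        pixel_size_nm=float(pixel_size_nm),
    )


@dataclass
class RawSIMStack:
    """A 9-frame SIM acquisition: 3 pattern orientations × 3 phases.

    ``frames`` has shape (3, 3, rows, cols), orientation-major,
    phase-minor.  Intensities are non-negative floats.
    """

    frames: np.ndarray
    orientations_deg: np.ndarray
    nominal_phases_rad: np.ndarray
    optical: OpticalParams

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.orientations_deg = np.asarray(self.orientations_deg, dtype=np.float64)
        self.nominal_phases_rad = np.asarray(self.nominal_phases_rad, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[:2] != (3, 3):
            raise ValueError("frames must have shape (3, 3, rows, cols)")
        if self.frames.shape[2:] != tuple(self.optical.image_shape):
            raise ValueError("frame shape disagrees with optical.image_shape")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.orientations_deg.shape != (3,):
            raise ValueError("exactly 3 orientations required")
        if self.nominal_phases_rad.shape != (3,):
            raise ValueError("exactly 3 nominal phases required")
        wrapped = np.mod(self.orientations_deg, 180.0)
        if len({round(a, 6) for a in wrapped}) != 3:
            raise ValueError("orientations must be pairwise distinct")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[2:]

    def frames_for_orientation(self, d: int) -> np.ndarray:
        return self.frames[d]


@dataclass
class SRImage:
    """Super-resolution reconstruction g(r) at 2× the raw sampling."""

    pixels: np.ndarray
    pixel_size_nm: float
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SR image must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    def clipped(self) -> np.ndarray:
        """Display copy with negative overshoot removed."""
        return np.clip(self.pixels, 0.0, None)


# --------------------------------------------------------------------------
# Stack I/O: multi-page TIFF + flat key/value sidecar.
# Multi-page TIFF tag dialects vary across writers, so acquisition metadata
# lives in a plain-text sidecar next to the TIFF.

_SIDECAR_SUFFIX = ".meta.txt"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def write_stack_tiff(path: str | Path, stack: RawSIMStack) -> None:
    """Write a 9-page float32 TIFF plus its metadata sidecar."""
    path = Path(path)
    pages = stack.frames.reshape(9, *stack.shape).astype(np.float32)
    tifffile.imwrite(path, pages, photometric='minisblack')
    meta = {
        "pixel_size_nm": stack.optical.pixel_size_nm,
        "emission_wavelength_nm": stack.optical.emission_wavelength_nm,
        "numerical_aperture": stack.optical.numerical_aperture,
        "orientations_deg": " ".join(f"{a:.10g}" for a in stack.orientations_deg),
        "phases_rad": " ".join(f"{p:.12g}" for p in stack.nominal_phases_rad),
    }
    lines = [f"{k}: {v}" for k, v in meta.items()]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict:
    """Parse the flat key/value sidecar written next to a stack TIFF."""
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta: dict = {}
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or ":" not in line:
            continue
        key, value = line.split(":", 1)
        meta[key.strip()] = value.strip()
    required = {
        "pixel_size_nm",
        "emission_wavelength_nm",
        "numerical_aperture",
        "orientations_deg",
        "phases_rad",
    }
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"sidecar missing keys: {sorted(missing)}")
    return meta


def read_stack_tiff(path: str | Path, config: dict | None = None) -> RawSIMStack:
    """Read a 9-page TIFF stack; metadata from `config` or the sidecar.

    16-bit unsigned pages are promoted to float in [0, 1] by dividing by
    65535; float pages are used as stored.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim != 3 or pages.shape[0] != 9:
        n = pages.shape[0] if pages.ndim == 3 else 1
        raise ValueError(f"expected a 9-page TIFF, found {n} pages")
    if pages.dtype == np.uint16:
        pages = pages.astype(np.float64) / 65535.0
    elif pages.dtype == np.uint8:
        pages = pages.astype(np.float64) / 255.0
    else:
        pages = pages.astype(np.float64)
    meta = dict(config) if config is not None else read_sidecar(path)
    optical = OpticalParams(
        emission_wavelength_nm=float(meta["emission_wavelength_nm"]),
        numerical_aperture=float(meta["numerical_aperture"]),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        image_shape=pages.shape[1:],
    )
    orientations = _parse_triplet(meta["orientations_deg"])
    phases = _parse_triplet(meta["phases_rad"])
    return RawSIMStack(
        frames=pages.reshape(3, 3, *pages.shape[1:]),
        orientations_deg=orientations,
        nominal_phases_rad=phases,
        optical=optical,
    )


def _parse_triplet(value) -> np.ndarray:
    if isinstance(value, str):
        parts = value.replace(",", " ").split()
    else:
        parts = list(value)
    arr = np.asarray([float(p) for p in parts], dtype=np.float64)
    if arr.shape != (3,):
        raise ValueError(f"expected 3 values, got {arr.size}")
    return arr
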