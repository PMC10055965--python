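"""Spectral band separation: the per-orientation 3×3 phase system.

Three frames of one orientation, acquired at phases φ1..φ3, mix the
order-0 and order-±1 spectral components through

    Ẽ_{d,φj}(k) = I0·[1, (m/2)e^{-iφj}, (m/2)e^{+iφj}] · [S0, S+1, S−1]ᵀ (+ D̃bg)

with S0 = C̃(k)H̃(k), S+1 = C̃(k+p_d)H̃(k), S−1 = C̃(k−p_d)H̃(k).  Inverting
the 3×3 matrix recovers the bands.  Because the inverse's first row has
weights summing to 1 while the other rows sum to 0, any phase-independent
additive field (the defocus background) lands entirely in S0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MixingMatrix",
    "SpectralBands",
    "build_separation_matrix",
    "separate_bands",
    "remix_bands",
    "frame_spectra",
]


class SingularMatrixError(ValueError):
    """Raised when the phase system cannot be inverted."""


@dataclass
class MixingMatrix:
    """The 3×3 phase-mixing matrix and its conditioning record."""

    matrix: np.ndarray
    phases: np.ndarray
    modulation: float
    condition_number: float

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class SpectralBands:
    """Separated complex spectra of one orientation (DC-centered, un-shifted)."""

    s0: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray

    def __post_init__(self) -> None:
        if not (self.s0.shape == self.s_plus.shape == self.s_minus.shape):
            raise ValueError("bands must share one grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.s0.shape


def build_separation_matrix(phases, modulation: float) -> MixingMatrix:
    """Rows [1, (m/2)e^{-iφj}, (m/2)e^{+iφj}] for the acquisition phases.

    Raises ``SingularMatrixError`` for repeated phases (mod 2π) or m = 0.
    """
    phases = np.asarray(phases, dtype=np.float64)
    if phases.shape != (3,):
        raise ValueError("exactly 3 phases required")
    if modulation <= 0:
        raise SingularMatrixError("modulation depth m = 0 gives zero columns")
    wrapped = np.mod(phases, 2 * np.pi)
    for a in range(3):
        for b in range(a + 1, 3):
            delta = np.mod(wrapped[a] - wrapped[b], 2 * np.pi)
            if min(delta, 2 * np.pi - delta) < 1e-9:
                raise SingularMatrixError("phases must be pairwise distinct modulo 2π")
    half_m = modulation / 2.0
    matrix = np.column_stack(
        [
            np.ones(3, dtype=np.complex128),
            half_m * np.exp(-1j * phases),
            half_m * np.exp(+1j * phases),
        ]
    )
    cond = float(np.linalg.cond(matrix))
    return MixingMatrix(matrix=matrix, phases=phases, modulation=float(modulation), condition_number=cond)


def frame_spectra(frames: np.ndarray) -> np.ndarray:
    """DC-centered FFTs of a (3, rows, cols) set of real frames."""
    return np.fft.fftshift(np.fft.fft2(np.asarray(frames, dtype=np.float64)), axes=(-2, -1))


def separate_bands(spectra: np.ndarray, matrix: MixingMatrix, intensity: float = 1.0) -> SpectralBands:
    """Solve the 3×3 system per pixel (as three weighted frame sums).

    ``spectra`` is the (3, rows, cols) complex array of DC-centered frame
    spectra of one orientation; the result is divided by I0.
    """
    spectra = np.asarray(spectra)
    if spectra.ndim != 3 or spectra.shape[0] != 3:
        raise ValueError("expected 3 frame spectra of one orientation")
    if intensity <= 0:
        raise ValueError("intensity I0 must be positive")
    weights = matrix.inverse  # (3, 3): bands × frames
    bands = np.tensordot(weights, spectra, axes=(1, 0)) / intensity
    return SpectralBands(s0=bands[0], s_plus=bands[1], s_minus=bands[2])


def remix_bands(bands: SpectralBands, matrix: MixingMatrix, intensity: float = 1.0) -> np.ndarray:
    """Forward-mix separated bands back into the 3 frame spectra."""
    stacked = np.stack([bands.s0, bands.s_plus, bands.s_minus])
    return intensity * np.tensordot(matrix.matrix, stacked, axes=(1, 0))
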