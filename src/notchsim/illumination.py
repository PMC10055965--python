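"""Estimation of the illumination pattern parameters from a raw stack.

The fringe wave vector is recovered from the normalized cross-power
(phase-only cross-correlation) of the order-0 and order-+1 bands,
separated with nominal phases: whitening every spectral sample to unit
magnitude removes the sample's colored spectrum and the OTF envelope, so
the correlation over relative band shifts peaks only at the fringe
frequency p_d.  The integer-pixel peak is refined by local zoomed-DFT
upsampling of the cross-power.  Phases come from the argument of each
raw-frame spectrum at the sub-pixel location p̂ (phase-of-peak, with the
object-leakage offset removed via the 2π/3 phase-sum identity), and the
modulation depth from a least-squares amplitude ratio of the order-±1
bands to the shifted order-0 band over the OTF overlap region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NM_PER_UM, RawSIMStack
from .bands import SpectralBands, build_separation_matrix, frame_spectra, separate_bands
from .forward_model import IlluminationParams, OTFModel

__all__ = [
    "EstimationError",
    "EstimatedIllumination",
    "estimate_wavevector",
    "estimate_phases",
    "estimate_modulation",
    "estimate_illumination",
]

# OTF support floor for overlap pixels in the modulation fit
OTF_FLOOR = 0.05
_NOMINAL_PHASES = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])


class EstimationError(RuntimeError):
    """Raised when no usable fringe information is present."""


def _edge_window(shape: tuple[int, int], alpha: float = 0.25) -> np.ndarray:
    """Separable Tukey window; suppresses the FFT leakage streaks that a
    non-periodic field of view would otherwise imprint on the correlation."""
    from scipy.signal.windows import tukey

    wy = tukey(shape[0], alpha)
    wx = tukey(shape[1], alpha)
    return np.outer(wy, wx)


@dataclass
class EstimatedIllumination:
    """Per-orientation illumination estimates recovered from data."""

    wave_vectors: np.ndarray  # (3, 2) cycles/µm
    phases: np.ndarray  # (3, 3) rad
    modulation: float
    scores: np.ndarray  # (3,) peak-correlation scores
    residual_px: np.ndarray  # (3,) sub-pixel refinement step actually applied

    def to_params(self, intensity: float = 1.0) -> IlluminationParams:
        return IlluminationParams(
            wave_vectors=self.wave_vectors,
            phases=self.phases,
            modulation=float(np.clip(self.modulation, 1e-3, 1.0)),
            intensity=intensity,
        )


def _zoom_dft(field: np.ndarray, qy: np.ndarray, qx: np.ndarray) -> np.ndarray:
    """Evaluate the DFT of `field` on an arbitrary (fractional) frequency
    grid given in frequency-pixel units."""
    n0, n1 = field.shape
    ey = np.exp(-2j * np.pi * np.outer(qy, np.arange(n0)) / n0)
    ex = np.exp(-2j * np.pi * np.outer(qx, np.arange(n1)) / n1)
    return ey @ field @ ex.T


def estimate_wavevector(
    frames: np.ndarray,
    otf: OTFModel,
    nominal_phases: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Estimate the fringe wave vector of one orientation.

    Parameters
    ----------
    frames : (3, rows, cols)
        The three phase frames of one orientation.
    otf : OTFModel
        System OTF (provides the cutoff and the grid/pixel bookkeeping).

    Returns ``(p_hat, score, residual_px)``: ``p_hat = (px, py)`` in
    cycles/µm canonicalized to the upper half-plane, a peak-correlation
    score, and the sub-pixel refinement step (frequency pixels).
    Raises ``EstimationError`` when no correlation peak rises above the
    noise floor (e.g. an m = 0 acquisition).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] != 3:
        raise ValueError("expected the 3 phase frames of one orientation")
    rows, cols = frames.shape[1:]
    phases = _NOMINAL_PHASES if nominal_phases is None else np.asarray(nominal_phases)
    # separation with unit carrier coefficients (m/2 -> 1): the ±1 bands
    # then carry (m/2)·C̃(k±p)H̃(k)
    matrix = build_separation_matrix(phases, 2.0)
    bands = separate_bands(frame_spectra(frames), matrix)
    # the coarse search runs on edge-windowed frames (windowing suppresses
    # the field-of-view leakage streaks that otherwise dominate the
    # correlation plane); the sub-pixel refinement runs on the unwindowed
    # bands, whose content relation is not blurred by the window kernel
    windowed_bands = separate_bands(
        frame_spectra(frames * _edge_window((rows, cols))[None]), matrix
    )

    # normalized cross-power of the order-0 and order-+1 bands over
    # relative frequency shifts.  Normalizing every spectral sample to
    # unit magnitude (phase-only correlation) removes the sample's colored
    # spectrum and the OTF envelope, so the only coherent alignment is the
    # fringe shift p, where the band contents agree pixel-by-pixel.
    support = otf.values > 0.03
    n_corr = rows * cols

    def cross_field(b, order):
        g0 = _phase_normalize(b.s0, support)
        g1 = _phase_normalize(b.s_plus if order > 0 else b.s_minus, support)
        return np.fft.ifft2(np.fft.ifftshift(g0)) * np.conj(
            np.fft.ifft2(np.fft.ifftshift(g1))
        )

    cross_coarse = cross_field(windowed_bands, +1)
    # scale restores correlation counts: the peak equals the number of
    # coherently agreeing spectral samples (≈ the band-overlap area)
    corr = np.fft.fftshift(np.fft.fft2(cross_coarse)) * n_corr
    mag = np.abs(corr)
    dx_um = otf.grid.pixel_size_nm / NM_PER_UM
    grid = otf.grid
    kem = otf.cutoff
    # the fringe frequency of a SIM acquisition sits in the outer half of
    # the OTF support; restricting the search there also excludes the
    # residue that camera-floor clipping leaks around DC
    mask = (grid.radial_magnitude > 0.5 * kem) & (grid.radial_magnitude <= 1.02 * kem)
    if not mask.any():
        raise EstimationError("OTF support too small for a correlation search")
    masked = np.where(mask, mag, 0.0)
    peak_val = masked.max()
    # a fringe-free stack gives a random-phasor walk whose masked maximum
    # scales like sqrt(support size); a genuine peak is coherent over the
    # band overlap and far exceeds it
    noise_floor = 6.0 * np.sqrt(float(np.sum(support)))
    if not peak_val > noise_floor:
        raise EstimationError("no correlation peak above the noise floor (m = 0?)")
    iy, ix = np.unravel_index(int(masked.argmax()), masked.shape)
    qy0 = float(iy - rows // 2)
    qx0 = float(ix - cols // 2)

    # sub-pixel refinement: local zoomed-DFT upsampling of the cross-power
    # around the integer peak (×20, then two further ×~20 stages so the
    # search grid is never the accuracy limit).  The order-−1 band is the
    # conjugate mirror of the order-+1 band for real frames, so it adds no
    # independent information and only the +1 band is correlated.
    cross_fine = cross_field(bands, +1)
    qy, qx = qy0, qx0
    for half, step in ((1.0, 0.05), (0.06, 0.0025), (0.004, 0.0002)):
        gy = np.arange(qy - half, qy + half + step / 2, step)
        gx = np.arange(qx - half, qx + half + step / 2, step)
        local = np.abs(_zoom_dft(cross_fine, gy, gx))
        jy, jx = np.unravel_index(int(local.argmax()), local.shape)
        qy, qx = float(gy[jy]), float(gx[jx])
    score = float(peak_val / max(np.sum(support), 1))
    residual = float(np.hypot(qy - qy0, qx - qx0))

    p_hat = np.array([qx / (cols * dx_um), qy / (rows * dx_um)])
    if p_hat[1] < 0 or (abs(p_hat[1]) < 1e-12 and p_hat[0] < 0):
        p_hat = -p_hat
    return p_hat, score, residual


def _phase_normalize(spectrum: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Unit-magnitude copy of a spectrum, zero outside the OTF support."""
    out = np.zeros_like(spectrum)
    nz = support & (np.abs(spectrum) > 0)
    out[nz] = spectrum[nz] / np.abs(spectrum[nz])
    return out


_PREWHITEN_SIGMA_PX = 3.0


def _dc_notch(grid, sigma_px: float = _PREWHITEN_SIGMA_PX) -> np.ndarray:
    """Smooth high-pass, 0 at DC: removes the order-0 band's dominant DC
    cone before sub-pixel interpolation (its trigonometric-interpolation
    ringing otherwise contaminates the whole shifted band)."""
    r_px = grid.radial_magnitude / grid.spacing[0]
    return 1.0 - np.exp(-(r_px**2) / (2.0 * sigma_px**2))


def estimate_phases(
    frames: np.ndarray, p_hat: np.ndarray, pixel_size_nm: float
) -> np.ndarray:
    """Phase-of-peak estimates: arg of each raw-frame spectrum at p̂.

    The spectrum is evaluated at the sub-pixel location by a direct DFT
    with the continuous frequency p̂; the frames are edge-windowed first
    so that the leakage tail of the (much larger) DC component does not
    contaminate the fringe peak.  Results are reported modulo 2π.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] != 3:
        raise ValueError("expected the 3 phase frames of one orientation")
    p_hat = np.asarray(p_hat, dtype=np.float64)
    if np.hypot(*p_hat) <= 0:
        raise ValueError("wave vector at DC carries no phase information")
    rows, cols = frames.shape[1:]
    dx_um = pixel_size_nm / NM_PER_UM
    windowed = frames * _edge_window((rows, cols))[None]
    ex = np.exp(-2j * np.pi * p_hat[0] * np.arange(cols) * dx_um)
    ey = np.exp(-2j * np.pi * p_hat[1] * np.arange(rows) * dx_um)
    values = np.einsum("r,jrc,c->j", ey, windowed, ex)
    # The object's own spectral content at p̂ adds one common complex
    # offset to all three peak values; under the nominal 2π/3 protocol the
    # fringe terms sum to zero over the frames, so the mean is exactly
    # that offset and subtracting it removes the leakage bias.
    values = values - values.mean()
    return np.mod(np.angle(values), 2 * np.pi)


def estimate_modulation(
    bands: SpectralBands, p_hat: np.ndarray, otf: OTFModel
) -> float:
    """Modulation depth from the order-±1 / order-0 amplitude ratio.

    ``bands`` must come from a separation with unit carrier coefficients
    (matrix built with the (m/2) factors replaced by 1), so the ±1 bands
    carry (m/2)·C̃H̃ and m̂ = 2·|least-squares ratio|.

    The order-0 band is high-pass pre-filtered before its sub-pixel shift
    (its DC cone otherwise rings under trigonometric interpolation), and
    the least-squares ratio is solved with the interpolation-free order-±1
    side as the regressor, which avoids errors-in-variables attenuation.
    """
    from .reconstruct import shift_band

    grid = otf.grid
    h = otf.values
    notch = _dc_notch(grid)
    m_hats = []
    for sign, band in ((+1, bands.s_plus), (-1, bands.s_minus)):
        q = (sign * p_hat[0], sign * p_hat[1])
        # order-0 band sampled at k + sign·p, and the OTF centred at −sign·p
        s0_shifted = shift_band(bands.s0 * notch, (-q[0], -q[1]), grid)
        h_shifted = otf.shifted((-q[0], -q[1]))
        d_px = grid.radial_distance_from((-q[0], -q[1])) / grid.spacing[0]
        notch_shifted = 1.0 - np.exp(-(d_px**2) / (2.0 * _PREWHITEN_SIGMA_PX**2))
        mask = (h > OTF_FLOOR) & (h_shifted > OTF_FLOOR)
        if not mask.any():
            raise EstimationError("empty OTF overlap region")
        lhs = (band * h_shifted * notch_shifted)[mask]
        rhs = (s0_shifted * h)[mask]
        denom = np.sum(np.abs(lhs) ** 2)
        if denom == 0:
            m_hats.append(0.0)
            continue
        inv_ratio = np.sum(np.conj(lhs) * rhs).real / denom
        m_hats.append(0.0 if inv_ratio == 0 else 2.0 / abs(inv_ratio))
    return float(np.mean(m_hats))


def estimate_illumination(stack: RawSIMStack, otf: OTFModel) -> EstimatedIllumination:
    """Estimate wave vectors, phases, and modulation for all orientations."""
    wave_vectors = np.zeros((3, 2))
    phases = np.zeros((3, 3))
    scores = np.zeros(3)
    residuals = np.zeros(3)
    m_per_d = np.zeros(3)
    for d in range(3):
        frames = stack.frames_for_orientation(d)
        p_hat, score, residual = estimate_wavevector(frames, otf)
        phi = estimate_phases(frames, p_hat, stack.optical.pixel_size_nm)
        matrix = build_separation_matrix(phi, 2.0)
        bands = separate_bands(frame_spectra(frames), matrix)
        m_per_d[d] = estimate_modulation(bands, p_hat, otf)
        wave_vectors[d] = p_hat
        phases[d] = phi
        scores[d] = score
        residuals[d] = residual
    return EstimatedIllumination(
        wave_vectors=wave_vectors,
        phases=phases,
        modulation=float(np.mean(m_per_d)),
        scores=scores,
        residual_px=residuals,
    )
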