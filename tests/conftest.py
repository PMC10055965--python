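"""Shared fixtures: optics, grids, phantoms, and simulated stacks."""

import numpy as np
import pytest

import notchsim as ns

PIXEL_NM = 40.0


@pytest.fixture(scope="session")
def optical128():
    return ns.OpticalParams(
        emission_wavelength_nm=520.0,
        numerical_aperture=1.5,
        pixel_size_nm=PIXEL_NM,
        image_shape=(128, 128),
    )


@pytest.fixture(scope="session")
def grid128(optical128):
    return ns.make_frequency_grid(optical128.image_shape, optical128.pixel_size_nm)


@pytest.fixture(scope="session")
def otf128(optical128, grid128):
    return ns.make_otf(optical128, grid128)


def filament_sample(n_px: int, seed: int, margin: float = 10.0) -> ns.SampleImage:
    """Filament phantom rendered at 2× and block-averaged to the raw grid."""
    fine, _ = ns.make_phantom(
        "filaments",
        (2 * n_px, 2 * n_px),
        {"n": 8, "margin": 2 * margin},
        seed=seed,
        pixel_size_nm=PIXEL_NM / 2,
    )
    return ns.SampleImage(ns.downsample2(fine.density), PIXEL_NM)


def upper_half_plane_illum(optical, frac: float, angle_deg: float, modulation: float,
                           phase0: float = 0.3) -> ns.IlluminationParams:
    """Three distinct orientations with the first wave vector controlled."""
    mag = frac * optical.cutoff
    a = np.deg2rad(angle_deg)
    wv = mag * np.array(
        [
            [np.cos(a), np.sin(a)],
            [np.cos(a + 2.09), np.sin(a + 2.09)],
            [np.cos(a - 2.09), np.sin(a - 2.09)],
        ]
    )
    phases = phase0 + np.tile(np.arange(3) * 2 * np.pi / 3, (3, 1))
    return ns.IlluminationParams(wave_vectors=wv, phases=phases, modulation=modulation)


@pytest.fixture(scope="session")
def noiseless_stack(optical128, otf128):
    """Noiseless 9-frame stack with known illumination (|p| = 0.8 kem, 60°)."""
    sample = filament_sample(128, seed=5)
    illum = upper_half_plane_illum(optical128, 0.8, 60.0, 0.9)
    stack = ns.simulate_raw_stack(sample, illum, otf128)
    return stack, illum, sample
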