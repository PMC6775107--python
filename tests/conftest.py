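"""Shared fixtures: standard media, small simulated scans, and a g-lookup.

Heavy simulations are session-scoped so the suite pays for each volume once.
All fixtures are fully deterministic (explicit seeds).
"""

from __future__ import annotations

import numpy as np
import pytest

from isoct import (AcquisitionSpec, LayerSpec, flat_phantom, simulate_volume)
from isoct.spectral import stft_cube
from isoct.surface import SurfaceMap
from isoct.wm_model import WMParams, amplitude_for_mu_s, build_g_lookup


@pytest.fixture(scope="session")
def tissue_wm() -> WMParams:
    """Tissue-like medium: mass fractal D=2.5, μ_s(600) = 150 cm⁻¹."""
    return amplitude_for_mu_s(150.0, 1000.0, 2.5, 600.0)


@pytest.fixture(scope="session")
def skeleton_wm() -> WMParams:
    """Skeleton-like medium: D=3.5, μ_s(600) = 250 cm⁻¹."""
    return amplitude_for_mu_s(250.0, 500.0, 3.5, 600.0)


@pytest.fixture(scope="session")
def rayleigh_wm() -> WMParams:
    """Rayleigh-type bead-standard stand-in: L_n ≪ λ."""
    return amplitude_for_mu_s(30.0, 20.0, 4.0, 600.0)


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionSpec:
    """Small, fast acquisition; phantom depths must stay within ~478 μm."""
    return AcquisitionSpec(n_k=1024, lateral_shape=(16, 16), rng_seed=42,
                           snr_db=None, rolloff_db_per_mm=0.0)


@pytest.fixture(scope="session")
def homogeneous_scan(tissue_wm, small_acq):
    """Speckled homogeneous tissue volume, surface at 100 μm."""
    ph = flat_phantom([LayerSpec(thickness_um=200.0, wm=tissue_wm)],
                      100.0, small_acq.lateral_shape)
    return simulate_volume(ph, small_acq)


@pytest.fixture(scope="session")
def homogeneous_cube(homogeneous_scan):
    return stft_cube(homogeneous_scan)


@pytest.fixture(scope="session")
def known_surface(small_acq):
    nx, ny = small_acq.lateral_shape
    return SurfaceMap(z_um=np.full((nx, ny), 100.0 * small_acq.medium_index),
                      valid=np.ones((nx, ny), dtype=bool))


@pytest.fixture(scope="session")
def g_lookup():
    """Coarse albedo → g table, sufficient for interpolation tests."""
    return build_g_lookup(
        D_grid=np.arange(1.5, 5.51, 0.1),
        albedo_grid=np.geomspace(1e-5, 1.0, 150),
        n_Ln=200,
    )
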