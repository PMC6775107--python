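"""Wavelength-resolved attenuation fitting and compensation.

Below the detected surface the band intensity follows Beer-Lambert,
I_b(z) ∝ μ_b e^{-2 μ_t (z - z_s)} (magnitude-squared convention), so a
weighted linear regression of ln I on depth over a fixed 90 μm window gives
μ_t(λ) = −slope/2 per band and per column.  Depth axes are stored as optical
path; the regression converts to geometric depth with the medium index so
μ_t is a physical coefficient (cm⁻¹) directly comparable to Mie theory.  The fitted attenuation is then
divided out of the cube so the depth-averaged band spectrum below the
surface is an unbiased estimate of the backscattering spectrum μ_b(λ), made
absolute (cm⁻¹) by a bead-standard calibration factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .spectral import SpectralCube
from .surface import SurfaceMap

__all__ = [
    "AttenuationMaps",
    "fit_mu_t",
    "compensate_attenuation",
    "mu_b_spectrum",
    "smooth_mu_t",
    "calibration_from_reference",
]

_UM_PER_CM = 1e4


@dataclass
class AttenuationMaps:
    """Per-band, per-column total attenuation μ_t (cm⁻¹) with fit diagnostics."""

    mu_t: np.ndarray  # (band, x, y)
    fit_r2: np.ndarray
    valid: np.ndarray  # (x, y)
    depth_window_um: float = 90.0
    floored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.floored is None:
            self.floored = np.zeros_like(self.mu_t, dtype=bool)

    def band_median(self) -> np.ndarray:
        out = np.full(self.mu_t.shape[0], np.nan)
        if self.valid.any():
            out = np.median(self.mu_t[:, self.valid], axis=1)
        return out

    def save(self, stem) -> None:
        """Multi-band 32-bit float TIFF + long-format CSV (x, y, band, mu_t, r2)."""
        import pandas as pd
        import tifffile

        stem = Path(stem)
        img = np.where(self.valid[None], self.mu_t, np.nan).astype(np.float32)
        tifffile.imwrite(stem.with_suffix(".tif"), img)
        b, x, y = np.meshgrid(*map(np.arange, self.mu_t.shape), indexing="ij")
        pd.DataFrame({
            "x": x.ravel(), "y": y.ravel(), "band": b.ravel(),
            "mu_t": self.mu_t.ravel(), "r2": self.fit_r2.ravel(),
        }).to_csv(stem.with_suffix(".csv"), index=False)


def _band_guard(cube: SpectralCube, surface_guard) -> np.ndarray:
    """Per-band fit-start offset below the surface (optical μm)."""
    from .spectral import band_psf_fwhm_um

    if surface_guard is None:
        return 1.5 * band_psf_fwhm_um(cube.band_centers, cube.band_fwhm)
    return np.broadcast_to(
        np.asarray(surface_guard, dtype=float), cube.band_centers.shape
    ).copy()


def _lateral_average(intensity: np.ndarray, kernel: int) -> np.ndarray:
    """Speckle-reduction box average over the lateral axes of (band, x, y, z)."""
    if kernel <= 1:
        return intensity
    return ndimage.uniform_filter(intensity, size=(1, kernel, kernel, 1),
                                  mode="nearest")


def fit_mu_t(
    cube: SpectralCube,
    surface: SurfaceMap,
    depth_window_um: float = 90.0,
    lateral_kernel: int = 3,
    min_samples: int = 5,
    intensity_floor: float = 1e-12,
    medium_index: float = 1.35,
    surface_guard: float | np.ndarray | None = None,
) -> AttenuationMaps:
    """Fit μ_t(band, x, y) by weighted log-linear regression below the surface.

    The regression of ln I on optical-path depth over a 90 μm window below
    the surface is weighted by the fitted intensity, de-emphasizing
    noise-floor voxels; the slope maps to μ_t = −slope/2.  The window starts
    a per-band guard distance below the surface (default 1.5× the band's
    axial PSF FWHM): inside the guard the PSF-blurred surface step flattens
    the decay and would bias μ_t low, more so for the wider PSFs at long
    wavelengths.  Columns with fewer than ``min_samples`` window voxels are
    invalid; negative fitted μ_t is floored at 0 and flagged.
    """
    if depth_window_um <= 2 * cube.dz_um:
        raise ValueError("depth window must exceed the axial sampling")
    n_b, nx, ny, _ = cube.intensity.shape
    guard = _band_guard(cube, surface_guard)
    avg = _lateral_average(cube.intensity, lateral_kernel)
    mu_t = np.full((n_b, nx, ny), np.nan)
    r2 = np.full((n_b, nx, ny), np.nan)
    floored = np.zeros((n_b, nx, ny), dtype=bool)
    valid = surface.valid.copy()
    z = cube.z_grid
    n_win = int(round(depth_window_um / cube.dz_um))
    bidx = np.arange(n_b)[:, None]
    for ix in range(nx):
        for iy in range(ny):
            if not valid[ix, iy]:
                continue
            z0 = surface.z_um[ix, iy]
            i0_b = np.searchsorted(z, z0 + guard)
            if np.any(i0_b + n_win > z.size) or n_win < min_samples:
                valid[ix, iy] = False
                continue
            widx = i0_b[:, None] + np.arange(n_win)[None, :]
            zz = z[widx] / medium_index / _UM_PER_CM  # geometric cm, (band, win)
            I = avg[bidx, ix, iy, widx]
            y_ln = np.log(np.clip(I, intensity_floor, None))
            # two-pass weighting: an unweighted fit first, then weights from
            # the *predicted* intensity.  Weighting by the observed intensity
            # itself correlates weights with the speckle residuals
            # (E[s ln s] > 0) and biases the slope steep.
            slope = syy = szz = szy = None
            w = np.ones_like(I)
            for _ in range(2):
                sw = w.sum(axis=1)
                zbar = (w * zz).sum(axis=1) / sw
                ybar = (w * y_ln).sum(axis=1) / sw
                dz_c = zz - zbar[:, None]
                dy_c = y_ln - ybar[:, None]
                szz = (w * dz_c**2).sum(axis=1)
                szy = (w * dz_c * dy_c).sum(axis=1)
                slope = szy / szz
                icept = ybar - slope * zbar
                w = np.exp(icept[:, None] + slope[:, None] * zz)
            syy = (w * dy_c**2).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2[:, ix, iy] = np.where(syy > 0, szy**2 / (szz * syy), 1.0)
            mt = -slope / 2.0
            neg = mt < 0
            floored[neg, ix, iy] = True
            mu_t[:, ix, iy] = np.where(neg, 0.0, mt)
    return AttenuationMaps(mu_t=mu_t, fit_r2=r2, valid=valid,
                           depth_window_um=depth_window_um, floored=floored)


def smooth_mu_t(atten: AttenuationMaps, kernel: int = 7) -> AttenuationMaps:
    """Laterally smoothed copy of the attenuation maps for compensation.

    Per-column μ_t estimates carry speckle noise whose variance grows with
    the band's axial PSF width; compensating each column with its own noisy
    μ̂_t inflates the window mean multiplicatively (Jensen bias) with a
    wavelength-dependent magnitude.  Averaging μ_t over a small lateral
    neighborhood before compensation suppresses the bias while the reported
    per-pixel maps stay untouched.  NaN-aware (normalized convolution over
    the valid mask).
    """
    if kernel <= 1:
        return atten
    filled = np.where(np.isfinite(atten.mu_t), atten.mu_t, 0.0)
    w = np.isfinite(atten.mu_t).astype(float)
    size = (1, kernel, kernel)
    num = ndimage.uniform_filter(filled, size=size, mode="nearest")
    den = ndimage.uniform_filter(w, size=size, mode="nearest")
    with np.errstate(invalid="ignore"):
        sm = np.where(den > 0, num / den, np.nan)
    return AttenuationMaps(mu_t=sm, fit_r2=atten.fit_r2, valid=atten.valid,
                           depth_window_um=atten.depth_window_um,
                           floored=atten.floored)


def compensate_attenuation(
    cube: SpectralCube, atten: AttenuationMaps, surface: SurfaceMap,
    medium_index: float = 1.35,
) -> SpectralCube:
    """Divide each voxel by the fitted overlying attenuation e^{-2 μ_t (z - z_s)}.

    Voxels above the surface are left untouched; invalid columns pass
    through unchanged.  Recorded in provenance.
    """
    z = cube.z_grid
    out = cube.intensity.copy()
    nx, ny = surface.z_um.shape
    for ix in range(nx):
        for iy in range(ny):
            if not (surface.valid[ix, iy] and atten.valid[ix, iy]):
                continue
            depth_cm = (np.clip(z - surface.z_um[ix, iy], 0.0, None)
                        / medium_index / _UM_PER_CM)
            out[:, ix, iy, :] *= np.exp(
                2.0 * atten.mu_t[:, ix, iy, None] * depth_cm[None, :]
            )
    return SpectralCube(
        intensity=out,
        band_centers=cube.band_centers,
        band_fwhm=cube.band_fwhm,
        z_grid=z,
        provenance=cube.provenance + ["compensate_attenuation"],
    )


def mu_b_spectrum(
    cube_compensated: SpectralCube,
    surface: SurfaceMap,
    depth_window_um: float = 90.0,
    calibration_scale=1.0,
    lateral_kernel: int = 1,
    surface_guard: float | np.ndarray | None = None,
):
    """Backscattering spectrum μ_b(band, x, y) from the compensated cube.

    Per column and band, the mean compensated intensity over the first
    ``depth_window_um`` of optical path below the surface (offset by the
    same per-band PSF guard as the attenuation fit), times the bead-standard
    calibration factor (scalar or per-band) that converts instrument units
    to cm⁻¹.  Returns (mu_b, valid).
    """
    z = cube_compensated.z_grid
    n_b, nx, ny, _ = cube_compensated.intensity.shape
    guard = _band_guard(cube_compensated, surface_guard)
    avg = _lateral_average(cube_compensated.intensity, lateral_kernel)
    mu_b = np.full((n_b, nx, ny), np.nan)
    valid = surface.valid.copy()
    n_win = int(round(depth_window_um / cube_compensated.dz_um))
    bidx = np.arange(n_b)[:, None]
    for ix in range(nx):
        for iy in range(ny):
            if not valid[ix, iy]:
                continue
            z0 = surface.z_um[ix, iy]
            i0_b = np.searchsorted(z, z0 + guard)
            if np.any(i0_b + n_win > z.size) or n_win < 1:
                valid[ix, iy] = False
                continue
            widx = i0_b[:, None] + np.arange(n_win)[None, :]
            mu_b[:, ix, iy] = avg[bidx, ix, iy, widx].mean(axis=1)
    scale = np.asarray(calibration_scale, dtype=float)
    if scale.ndim == 1:
        mu_b = mu_b * scale[:, None, None]
    else:
        mu_b = mu_b * scale
    return mu_b, valid


def calibration_from_reference(
    ref_cube: SpectralCube,
    ref_surface: SurfaceMap,
    known_mu_b: np.ndarray,
    depth_window_um: float = 90.0,
    medium_index: float = 1.35,
) -> np.ndarray:
    """Per-band scale factors from a scan of a standard with known μ_b(λ).

    The reference (e.g. an 80 nm polystyrene bead suspension, a Rayleigh-type
    scatterer) is processed with exactly the same attenuation-fit →
    compensate → window-average chain as a sample, so window and speckle
    biases cancel in the ratio known/measured.
    """
    from . import attenuation as _self  # same-module clarity for the chain

    atten = _self.fit_mu_t(ref_cube, ref_surface, depth_window_um,
                           medium_index=medium_index)
    # the standard is homogeneous by design: compensate every column with the
    # map-median μ_t per band so per-column fit noise cannot bias the mean
    med = atten.band_median()
    atten_med = AttenuationMaps(
        mu_t=np.broadcast_to(med[:, None, None], atten.mu_t.shape).copy(),
        fit_r2=atten.fit_r2, valid=atten.valid,
        depth_window_um=atten.depth_window_um, floored=atten.floored,
    )
    comp = _self.compensate_attenuation(ref_cube, atten_med, ref_surface,
                                        medium_index=medium_index)
    meas, valid = _self.mu_b_spectrum(comp, ref_surface, depth_window_um)
    if not valid.any():
        raise ValueError("reference scan has no valid columns")
    meas_band = np.nanmean(meas[:, valid], axis=1)
    known = np.asarray(known_mu_b, dtype=float)
    if known.shape != meas_band.shape:
        raise ValueError("known_mu_b must have one value per band")
    return known / meas_band
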