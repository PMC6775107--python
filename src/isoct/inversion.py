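"""Spectral inversion: μ_t decomposition, fractal-dimension fit, g from albedo.

Three estimators make up the inverse problem:

1.  **Decomposition of μ_t(λ)** into absorption and scattering.  With every
    spectrum max-normalized (the * convention), the model is

        μ_t*(λ_i) ≈ c_a μ_a*(λ_i) + c_s μ_s*(λ_i; D, L_n),

    minimized as a sum of squared differences by multi-start Nelder-Mead.
    Because the normalized objective fixes only the *shape*, the optimizer
    works in the scale-free parameterization (ρ = c_a/(c_a+c_s), D, ln L_n)
    and the coefficients are afterwards put in the canonical gauge where the
    model reaches the normalized spectrum's maximum (max_λ f = 1), from
    which the absolute coefficients follow by scaling with max μ_t:
    μ_a(λ) = c_a μ_a*(λ) max{μ_t}, μ_s(λ) = c_s μ_s*(λ) max{μ_t}.  Reported
    c_a, c_s are clipped to the [0, ½] box (flagged when clipping occurred);
    the absolute spectra use the unclipped canonical values.  The 660 nm
    chlorophyll-a feature is what makes the split identifiable — a smooth
    μ_a* leaves the two components degenerate.

2.  **D from the backscattering spectrum.**  The OCT amplitude spectrum
    scales as λ^{D/2−2}, so an ordinary least-squares fit of ln √μ_b on ln λ
    gives D = 2·(slope + 2) with a per-pixel standard error.

3.  **g from the albedo.**  α = μ_b/μ_s at an absorption-quiet reference
    band (nearest 620 nm) enters the precomputed Born-model lookup g(α, D)
    by bilinear interpolation; out-of-support queries are masked, never
    extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from . import pigment as _pigment
from . import wm_model as _wm
from .attenuation import (AttenuationMaps, compensate_attenuation,
                          mu_b_spectrum, smooth_mu_t)
from .spectral import SpectralCube
from .surface import SurfaceMap

__all__ = [
    "DecompositionResult",
    "FractalMap",
    "PropertyMaps",
    "decompose_mu_t",
    "decomposition_cost",
    "fit_D_from_mub",
    "fit_D_map",
    "g_from_albedo",
    "build_property_maps",
]

_D_BOUNDS = (1.3, 5.8)
_LN_BOUNDS = (20.0, 5000.0)  # nm


@dataclass
class DecompositionResult:
    """Outcome of one μ_t(λ) → (μ_a, μ_s) spectral decomposition.

    ``c_a``/``c_s`` are the reported fractional contributions, bounded to
    [0, ½]; ``c_a_canonical``/``c_s_canonical`` are the unclipped values in
    the gauge max_λ(c_a μ_a* + c_s μ_s*) = 1 that the absolute spectra are
    built from.
    """

    c_a: float
    c_s: float
    D: float
    Ln: float
    mu_a: np.ndarray
    mu_s: np.ndarray
    cost: float
    converged: bool
    c_a_canonical: float = None  # type: ignore[assignment]
    c_s_canonical: float = None  # type: ignore[assignment]
    clipped: bool = False
    start_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.c_a_canonical is None:
            self.c_a_canonical = self.c_a
        if self.c_s_canonical is None:
            self.c_s_canonical = self.c_s


def _model_star(
    rho: float, D: float, Ln: float, lam: np.ndarray,
    mu_a_star: np.ndarray, medium_index: float,
) -> np.ndarray:
    f = rho * mu_a_star + (1.0 - rho) * _wm.mu_s_shape_star(lam, D, Ln, medium_index)
    return f / f.max()


def decomposition_cost(
    mu_t_star: np.ndarray,
    lambda_grid: np.ndarray,
    c_a: float,
    c_s: float,
    D: float,
    Ln: float,
    chl_reference: Optional[_pigment.PigmentSpectrum] = None,
    medium_index: float = _wm.DEFAULT_MEDIUM_INDEX,
) -> float:
    """Sum of squared residuals |μ_t*(λ_i) − c_a μ_a*(λ_i) − c_s μ_s*(λ_i)|².

    Independent recomputation of the decomposition objective; at a returned
    result's canonical coefficients it equals the stored ``cost`` exactly.
    """
    ref = chl_reference or _pigment.chlorophyll_a_reference()
    mu_a_star = ref.shape_at(lambda_grid)
    f = c_a * mu_a_star + c_s * _wm.mu_s_shape_star(lambda_grid, D, Ln, medium_index)
    return float(np.sum((np.asarray(mu_t_star) - f) ** 2))


def decompose_mu_t(
    mu_t_spectrum: np.ndarray,
    lambda_grid: np.ndarray,
    chl_reference: Optional[_pigment.PigmentSpectrum] = None,
    skeleton_mode: bool = False,
    n_starts: int = 8,
    seed: int = 0,
    medium_index: float = _wm.DEFAULT_MEDIUM_INDEX,
) -> DecompositionResult:
    """Decompose a μ_t(λ) spectrum into chlorophyll absorption and WM scattering.

    Multi-start Nelder-Mead (Latin-hypercube starts over the bounds, fixed
    seed) over (ρ, D, ln L_n); ties in cost break toward smaller D.  In
    skeleton mode absorption is disabled (ρ ≡ 0) and only (D, L_n) are fit.
    Non-convergence is flagged and the best candidate still returned.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    mu_t = np.asarray(mu_t_spectrum, dtype=float)
    if lam.size < 10:
        raise ValueError("need at least 10 spectral bands for decomposition")
    peak = float(mu_t.max())
    if not (peak > 0):
        raise ValueError("μ_t spectrum must be positive somewhere")
    mu_t_star = mu_t / peak
    ref = chl_reference or _pigment.chlorophyll_a_reference()
    mu_a_star = ref.shape_at(lam)

    lo = np.array([0.0, _D_BOUNDS[0], np.log(_LN_BOUNDS[0])])
    hi = np.array([1.0, _D_BOUNDS[1], np.log(_LN_BOUNDS[1])])

    def cost_vec(p):
        rho = 0.0 if skeleton_mode else p[0]
        f = _model_star(rho, p[1], np.exp(p[2]), lam, mu_a_star, medium_index)
        pen = np.sum(np.clip(lo - p, 0, None) ** 2 + np.clip(p - hi, 0, None) ** 2)
        return float(np.sum((mu_t_star - f) ** 2)) + 1e3 * pen

    rng = np.random.default_rng(seed)
    starts = _latin_hypercube(rng, n_starts, lo, hi)
    candidates = []
    n_ok = 0
    for p0 in starts:
        res = optimize.minimize(
            cost_vec, p0, method="Nelder-Mead",
            options=dict(xatol=1e-7, fatol=1e-12, maxiter=2000),
        )
        p = np.clip(res.x, lo, hi)
        candidates.append((float(cost_vec(p)), p))
        n_ok += bool(res.success)
    costs = np.array([c for c, _ in candidates])
    best_cost = costs.min()
    # tie-break among near-equal costs: smallest D
    near = [p for c, p in candidates if c <= best_cost + 1e-12]
    p_best = min(near, key=lambda p: p[1])
    rho, D, Ln = (0.0 if skeleton_mode else p_best[0]), p_best[1], np.exp(p_best[2])

    f_raw = rho * mu_a_star + (1.0 - rho) * _wm.mu_s_shape_star(lam, D, Ln, medium_index)
    F = float(f_raw.max())
    c_a_can, c_s_can = rho / F, (1.0 - rho) / F
    clipped = c_a_can > 0.5 or c_s_can > 0.5
    mu_a = c_a_can * mu_a_star * peak
    mu_s = c_s_can * _wm.mu_s_shape_star(lam, D, Ln, medium_index) * peak
    cost = decomposition_cost(mu_t_star, lam, c_a_can, c_s_can, D, Ln, ref,
                              medium_index)
    # dispersion of per-start solutions in ρ: identifiability diagnostic.
    # starts are "equally acceptable" when their RMS band residual is within
    # noise of the best — a wide spread in ρ among them means the
    # absorption/scattering split is not identified by the spectrum.
    accept = max(best_cost * 1.5, best_cost + 1e-3)
    rhos = np.array([p[0] for c, p in candidates if c <= accept])
    dispersion = float(rhos.std()) if rhos.size > 1 and not skeleton_mode else 0.0
    return DecompositionResult(
        c_a=min(c_a_can, 0.5), c_s=min(c_s_can, 0.5),
        D=float(D), Ln=float(Ln), mu_a=mu_a, mu_s=mu_s,
        cost=cost, converged=n_ok > 0,
        c_a_canonical=c_a_can, c_s_canonical=c_s_can,
        clipped=bool(clipped), start_dispersion=dispersion,
    )


def _latin_hypercube(rng, n, lo, hi):
    d = lo.size
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T + rng.random((n, d))) / n
    return lo + u * (hi - lo)


def fit_D_from_mub(
    mu_b_spectrum: np.ndarray,
    lambda_grid: np.ndarray,
    scale: str = "amplitude",
    min_bands: int = 6,
):
    """Fractal dimension from the backscattering spectrum's power law.

    Ordinary least squares of ln(spectrum) on ln λ; on the amplitude scale
    (the OCT signal spectrum, default) the slope is D/2 − 2, so
    D = 2·(slope + 2); on the intensity scale (μ_b in cm⁻¹, i.e. the square
    of the amplitude spectrum) the slope is D − 4, so D = slope + 4.
    Nonpositive bands are dropped; fewer than ``min_bands`` remaining makes
    the fit invalid.  Returns (D, standard error of D, valid flag).
    """
    s = np.asarray(mu_b_spectrum, dtype=float)
    lam = np.asarray(lambda_grid, dtype=float)
    keep = np.isfinite(s) & (s > 0)
    if keep.sum() < min_bands:
        return np.nan, np.nan, False
    res = stats.linregress(np.log(lam[keep]), np.log(s[keep]))
    if scale == "amplitude":
        return 2.0 * (res.slope + 2.0), 2.0 * res.stderr, True
    if scale == "intensity":
        # ln μ_b = 2 ln √μ_b: same fit, half the slope on the amplitude scale
        return res.slope + 4.0, res.stderr, True
    raise ValueError(f"unknown scale {scale!r}")


def fit_D_map(
    mu_b_maps: np.ndarray,
    lambda_grid: np.ndarray,
    valid: np.ndarray,
    scale: str = "intensity",
):
    """Vectorized per-pixel D fit over μ_b(band, x, y).  Returns (D, se, ok)."""
    n_b, nx, ny = mu_b_maps.shape
    lam = np.log(np.asarray(lambda_grid, dtype=float))
    D = np.full((nx, ny), np.nan)
    se = np.full((nx, ny), np.nan)
    ok = np.zeros((nx, ny), dtype=bool)
    flat = mu_b_maps.reshape(n_b, -1)
    vflat = valid.reshape(-1)
    for j in np.nonzero(vflat)[0]:
        d, s, good = fit_D_from_mub(flat[:, j], np.exp(lam), scale=scale)
        D.flat[j], se.flat[j], ok.flat[j] = d, s, good
    return D, se, ok


def g_from_albedo(
    mu_b: np.ndarray,
    mu_s: np.ndarray,
    D: np.ndarray,
    lookup: _wm.GLookupTable,
):
    """Anisotropy g from the reflection albedo α = μ_b/μ_s and D.

    Bilinear interpolation in the precomputed Born-model table; pixels whose
    (α, D) fall outside the table's support — including μ_s ≤ 0 — are masked,
    never extrapolated.  Returns (g, valid_mask).
    """
    mu_b = np.asarray(mu_b, dtype=float)
    mu_s = np.asarray(mu_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_s > 0, mu_b / mu_s, np.nan)
    g, valid = lookup.lookup(alpha, D)
    return g, valid


@dataclass
class FractalMap:
    """Per-(x, y) structural and anisotropy maps."""

    D: np.ndarray
    D_se: np.ndarray
    g: np.ndarray
    valid: np.ndarray
    g_valid: np.ndarray
    D_decomposition: np.ndarray = None  # type: ignore[assignment]


@dataclass
class PropertyMaps:
    """Everything the pipeline knows per lateral position."""

    band_centers: np.ndarray
    mu_t: np.ndarray          # (band, x, y) cm⁻¹
    mu_b: np.ndarray          # (band, x, y) cm⁻¹ calibrated
    mu_s: np.ndarray          # (band, x, y) cm⁻¹ from decomposition
    mu_a: np.ndarray          # (band, x, y) cm⁻¹ from decomposition
    fractal: FractalMap
    chl_volumetric: np.ndarray  # mg cm⁻³
    chl_areal: np.ndarray       # μg cm⁻²
    valid: np.ndarray
    skeleton_mode: bool
    provenance: list[str] = field(default_factory=list)

    def median_summary(self) -> dict:
        """Map medians over valid pixels (the headline per-region numbers)."""
        v = self.valid
        out = {"n_valid": int(v.sum())}
        if not v.any():
            return out
        out["D_median"] = float(np.nanmedian(self.fractal.D[v]))
        gv = self.fractal.g_valid & v
        out["g_median"] = float(np.nanmedian(self.fractal.g[gv])) if gv.any() else np.nan
        out["mu_t_band_median"] = np.nanmedian(self.mu_t[:, v], axis=1)
        out["mu_s_band_median"] = np.nanmedian(self.mu_s[:, v], axis=1)
        if not self.skeleton_mode:
            out["chl_areal_median"] = float(np.nanmedian(self.chl_areal[v]))
        return out


def build_property_maps(
    cube: SpectralCube,
    surface: SurfaceMap,
    atten: AttenuationMaps,
    lookup: _wm.GLookupTable,
    calibration_scale=1.0,
    chl_reference: Optional[_pigment.PigmentSpectrum] = None,
    skeleton_mode: bool = False,
    depth_window_um: float = 90.0,
    decompose_block: int = 8,
    alpha_reference_nm: float = 620.0,
    n_starts: int = 8,
    seed: int = 0,
    medium_index: float = _wm.DEFAULT_MEDIUM_INDEX,
    compensation_smooth: int = 7,
) -> PropertyMaps:
    """Orchestrate the full per-pixel inversion.

    compensate → μ_b maps → per-pixel D (amplitude-scale power law);
    block-averaged μ_t → decomposition → μ_a, μ_s → chlorophyll; α at the
    absorption-quiet reference band with the μ_b-derived D → g lookup.
    Decomposition runs on ``decompose_block``² super-pixels of the
    (speckle-noisy) μ_t maps; results are broadcast back to pixels.
    """
    ref = chl_reference or _pigment.chlorophyll_a_reference()
    lam = cube.band_centers
    comp = compensate_attenuation(cube, smooth_mu_t(atten, compensation_smooth),
                                  surface, medium_index=medium_index)
    mu_b, valid = mu_b_spectrum(
        comp, surface, depth_window_um, calibration_scale, lateral_kernel=3
    )
    valid = valid & atten.valid & surface.valid
    # D per pixel from the amplitude spectrum √μ_b  (equivalently the
    # intensity-scale fit; see fit_D_from_mub)
    D_map, D_se, D_ok = fit_D_map(mu_b, lam, valid, scale="intensity")
    nx, ny = valid.shape
    n_b = lam.size

    mu_s_maps = np.full((n_b, nx, ny), np.nan)
    mu_a_maps = np.full((n_b, nx, ny), np.nan)
    chl_vol = np.full((nx, ny), np.nan)
    D_dec = np.full((nx, ny), np.nan)
    blk = max(int(decompose_block), 1)
    for bx in range(0, nx, blk):
        for by in range(0, ny, blk):
            sl = (slice(bx, bx + blk), slice(by, by + blk))
            m = valid[sl]
            if not m.any():
                continue
            mu_t_blk = np.nanmean(atten.mu_t[:, sl[0], sl[1]][:, m], axis=1)
            if not np.all(np.isfinite(mu_t_blk)) or mu_t_blk.max() <= 0:
                continue
            dec = decompose_mu_t(
                mu_t_blk, lam, ref, skeleton_mode=skeleton_mode,
                n_starts=n_starts, seed=seed, medium_index=medium_index,
            )
            mu_s_maps[:, sl[0], sl[1]][:, m] = dec.mu_s[:, None]
            mu_a_maps[:, sl[0], sl[1]][:, m] = dec.mu_a[:, None]
            D_dec[sl][m] = dec.D
            if not skeleton_mode:
                peak_idx = int(np.argmin(np.abs(lam - ref.peak_wavelength)))
                shape_at_band = ref.shape_at(lam[peak_idx])
                mu_a_peak = dec.mu_a[peak_idx] / max(shape_at_band, 1e-12)
                _, mass = _pigment.chl_volumetric(max(mu_a_peak, 0.0), ref)
                chl_vol[sl][m] = mass
    chl_areal = _pigment.chl_areal_density(chl_vol, depth_window_um)

    iband = int(np.argmin(np.abs(lam - alpha_reference_nm)))
    g_map, g_ok = g_from_albedo(mu_b[iband], mu_s_maps[iband], D_map, lookup)
    fr = FractalMap(D=D_map, D_se=D_se, g=g_map,
                    valid=valid & D_ok, g_valid=g_ok & valid,
                    D_decomposition=D_dec)
    prov = list(cube.provenance) + [
        f"build_property_maps: skeleton_mode={skeleton_mode}, "
        f"block={blk}, alpha_band={lam[iband]:.1f} nm, seed={seed}",
    ]
    if skeleton_mode:
        chl_vol = np.full((nx, ny), np.nan)
        chl_areal = np.full((nx, ny), np.nan)
    return PropertyMaps(
        band_centers=lam, mu_t=atten.mu_t, mu_b=mu_b,
        mu_s=mu_s_maps, mu_a=mu_a_maps, fractal=fr,
        chl_volumetric=chl_vol, chl_areal=chl_areal,
        valid=valid & D_ok, skeleton_mode=skeleton_mode, provenance=prov,
    )
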