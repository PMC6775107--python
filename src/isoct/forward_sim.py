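"""Forward simulation of spectral-domain OCT volumes from layered phantoms.

The simulator realizes exactly the signal model the inversion assumes: the
backscattered field amplitude from depth z at vacuum wavelength λ is

    A(z, λ) ∝ √(μ_b(λ, z)) · exp(−∫₀ᶻ μ_t(λ, z′) dz′) · rolloff(z) · speckle

and the interferogram at wavenumber k is the real part of the coherent sum of
scatterer contributions with round-trip phase 2 k n z.  Speckle is fully
developed: per-scatterer complex circular-Gaussian reflectivity, frozen
across wavenumber, drawn once per volume from the mandatory seed.

Phantoms are stacks of homogeneous layers under an arbitrary surface height
field (emulating coenosarc tissue over skeletal plates); each layer's optical
spectra derive from its Whittle-Matérn parameters and chlorophyll-a
concentration, or may be supplied directly (e.g. a Mie bead suspension).

Speckle-free ("ideal") mode produces the expectation of the band intensity —
the incoherent envelope μ_b e^{-2 μ_t z} rolloff² directly as a spectral cube
— because a single real interferogram cannot carry a deterministic
exponential envelope (coherent summation necessarily speckles).  It is the
reference the Beer-Lambert contract is exact against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import h5py
import numpy as np

from . import pigment as _pigment
from . import wm_model as _wm

__all__ = [
    "LayerSpec",
    "AcquisitionSpec",
    "PhantomVolume",
    "RawScan",
    "make_phantom",
    "flat_phantom",
    "simulate_aline",
    "simulate_volume",
    "simulate_ideal_cube",
    "mie_mu_t",
]

# re-export: the Mie standard is part of this module's validation surface
from .mie import mie_mu_t  # noqa: E402,F401

_UM_PER_CM = 1e4


@dataclass(frozen=True)
class LayerOptics:
    """Explicit per-layer spectra (cm⁻¹ as functions of vacuum λ in nm)."""

    mu_s: Callable[[np.ndarray], np.ndarray]
    mu_a: Callable[[np.ndarray], np.ndarray]
    mu_b: Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous phantom layer.

    ``chl_volumetric`` is the chlorophyll-a mass concentration in mg cm⁻³;
    skeleton-type layers must have zero (skeletal light absorption is treated
    as negligible relative to scattering).  ``backscatter_scale`` multiplies
    μ_b only (a reflectivity tweak that leaves attenuation untouched).
    """

    thickness_um: float
    wm: Optional[_wm.WMParams] = None
    chl_volumetric: float = 0.0
    backscatter_scale: float = 1.0
    kind: str = "tissue"  # "tissue" | "skeleton" | "custom"
    optics: Optional[LayerOptics] = None

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("layer thickness must be > 0")
        if self.chl_volumetric < 0:
            raise ValueError("chlorophyll concentration must be >= 0")
        if self.kind == "skeleton" and self.chl_volumetric != 0:
            raise ValueError("skeleton layers are non-absorbing (chl must be 0)")
        if self.wm is None and self.optics is None:
            raise ValueError("layer needs either WM parameters or explicit optics")

    def spectra(
        self,
        lam: np.ndarray,
        medium_index: float,
        collection_sr: float,
        chl_reference: Optional[_pigment.PigmentSpectrum] = None,
    ):
        """(μ_s, μ_a, μ_b, μ_t) in cm⁻¹ on the given vacuum-λ grid."""
        lam = np.asarray(lam, dtype=float)
        if self.optics is not None:
            mu_s = np.asarray(self.optics.mu_s(lam), dtype=float)
            mu_a = np.asarray(self.optics.mu_a(lam), dtype=float)
            mu_b = np.asarray(self.optics.mu_b(lam), dtype=float)
        else:
            mu_s = np.atleast_1d(
                _wm.mu_s_spectrum(self.wm, lam, medium_index, method="closed")
            )
            mu_b = np.atleast_1d(
                _wm.mu_b_spectrum_model(self.wm, lam, medium_index, collection_sr)
            )
            if self.chl_volumetric > 0:
                ref = chl_reference or _pigment.chlorophyll_a_reference()
                mu_a = _pigment.mu_a_from_concentration(self.chl_volumetric, lam, ref)
            else:
                mu_a = np.zeros_like(lam)
        mu_b = mu_b * self.backscatter_scale
        return mu_s, mu_a, mu_b, mu_s + mu_a


@dataclass(frozen=True)
class AcquisitionSpec:
    """Spectral-domain acquisition geometry and noise model.

    The wavenumber grid is uniform in k over [2π/λ_max, 2π/λ_min] with
    ``n_k`` samples (4,096-pixel line-scan camera by default).  ``snr_db``
    sets the band-intensity signal-to-noise ratio at the phantom surface
    (None = noiseless fringes).  A seed is mandatory: every stochastic
    output is reproducible from (phantom, acquisition, seed).
    """

    lambda_min: float = 520.0
    lambda_max: float = 720.0
    n_k: int = 4096
    lateral_shape: tuple[int, int] = (64, 64)
    pixel_pitch_um: float = 5.0
    rolloff_db_per_mm: float = -10.0
    snr_db: Optional[float] = None
    rng_seed: int = 0
    medium_index: float = _wm.DEFAULT_MEDIUM_INDEX
    collection_sr: float = _wm.DEFAULT_COLLECTION_SR
    scatterer_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lambda_min < self.lambda_max):
            raise ValueError("lambda_min must be < lambda_max")
        if self.n_k < 512:
            raise ValueError("n_k must be >= 512")

    @property
    def k_grid(self) -> np.ndarray:
        """Uniform vacuum wavenumber grid (nm⁻¹), strictly increasing."""
        return np.linspace(
            2.0 * np.pi / self.lambda_max, 2.0 * np.pi / self.lambda_min, self.n_k
        )

    @property
    def lambda_of_k(self) -> np.ndarray:
        return 2.0 * np.pi / self.k_grid

    @property
    def dk(self) -> float:
        k = self.k_grid
        return float(k[1] - k[0])

    @property
    def z_grid_um(self) -> np.ndarray:
        """Optical-path depth grid of the Fourier-transformed A-line (μm)."""
        m = np.arange(self.n_k // 2)
        return m * np.pi / (self.n_k * self.dk) * 1e-3

    def rolloff_amplitude(self, z_opt_um) -> np.ndarray:
        """Sensitivity decay as an amplitude factor at optical depth z."""
        z_mm = np.asarray(z_opt_um, dtype=float) * 1e-3
        return 10.0 ** (self.rolloff_db_per_mm * z_mm / 20.0)


@dataclass
class PhantomVolume:
    """Layer stack + surface height field with known ground-truth optics."""

    layers: tuple[LayerSpec, ...]
    surface_um: np.ndarray  # geometric surface depth per (x, y), μm
    chl_reference: _pigment.PigmentSpectrum = field(
        default_factory=_pigment.chlorophyll_a_reference
    )

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("phantom needs at least one layer")
        self.surface_um = np.asarray(self.surface_um, dtype=float)
        if not np.all(np.isfinite(self.surface_um)):
            raise ValueError("surface profile must be finite")

    @property
    def total_thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    def layer_boundaries_um(self) -> np.ndarray:
        """Depths of layer interfaces below the surface (geometric μm)."""
        return np.concatenate([[0.0], np.cumsum([l.thickness_um for l in self.layers])])

    def column_profiles(self, lam: np.ndarray, acq: AcquisitionSpec):
        """Per-scatterer property profiles shared by every column.

        Returns (z_rel_um, mu_t, mu_b, mu_a) where z_rel is the geometric
        depth below the surface and the spectra have shape (n_lambda, n_z).
        """
        dz = acq.scatterer_spacing_um
        z_rel = np.arange(dz / 2.0, self.total_thickness_um, dz)
        bounds = self.layer_boundaries_um()
        idx = np.searchsorted(bounds, z_rel, side="right") - 1
        idx = np.clip(idx, 0, len(self.layers) - 1)
        n_lam = len(lam)
        mu_t = np.empty((n_lam, z_rel.size))
        mu_b = np.empty_like(mu_t)
        mu_a = np.empty_like(mu_t)
        for li, layer in enumerate(self.layers):
            cols = idx == li
            if not np.any(cols):
                continue
            _, a, b, t = layer.spectra(
                lam, acq.medium_index, acq.collection_sr, self.chl_reference
            )
            mu_t[:, cols] = t[:, None]
            mu_b[:, cols] = b[:, None]
            mu_a[:, cols] = a[:, None]
        return z_rel, mu_t, mu_b, mu_a

    def ground_truth(self, band_centers: np.ndarray, acq: AcquisitionSpec) -> dict:
        """Per-layer reference spectra at the analysis band centers."""
        out = {"surface_um": self.surface_um, "layers": []}
        for layer in self.layers:
            mu_s, mu_a, mu_b, mu_t = layer.spectra(
                band_centers, acq.medium_index, acq.collection_sr, self.chl_reference
            )
            entry = {
                "kind": layer.kind,
                "thickness_um": layer.thickness_um,
                "chl_volumetric_mg_cm3": layer.chl_volumetric,
                "mu_s": mu_s, "mu_a": mu_a, "mu_b": mu_b, "mu_t": mu_t,
            }
            if layer.wm is not None:
                entry.update(An=layer.wm.An, Ln=layer.wm.Ln, D=layer.wm.D)
                entry["g"] = np.array([
                    _wm.anisotropy_g(layer.wm, wl, acq.medium_index, method="closed")
                    for wl in np.atleast_1d(band_centers)
                ])
            out["layers"].append(entry)
        return out


def make_phantom(
    layers: Sequence[LayerSpec],
    surface_um,
    chl_reference: Optional[_pigment.PigmentSpectrum] = None,
) -> PhantomVolume:
    """Assemble a layered phantom under the given surface height field."""
    kwargs = {}
    if chl_reference is not None:
        kwargs["chl_reference"] = chl_reference
    return PhantomVolume(layers=tuple(layers), surface_um=np.asarray(surface_um, float),
                         **kwargs)


def flat_phantom(
    layers: Sequence[LayerSpec],
    surface_depth_um: float,
    lateral_shape: tuple[int, int] = (64, 64),
    chl_reference: Optional[_pigment.PigmentSpectrum] = None,
) -> PhantomVolume:
    """Convenience constructor: flat surface at a single depth."""
    return make_phantom(
        layers, np.full(lateral_shape, float(surface_depth_um)), chl_reference
    )


@dataclass
class RawScan:
    """Wavenumber-domain interferogram volume (k, x, y) plus metadata."""

    fringes: np.ndarray
    acquisition: AcquisitionSpec
    ground_truth: Optional[dict] = None
    phantom: Optional[PhantomVolume] = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fringes)):
            raise ValueError("fringes must be finite")

    @property
    def k_grid(self) -> np.ndarray:
        return self.acquisition.k_grid

    def save(self, path) -> None:
        """Chunked HDF5 container: datasets ``fringes``, ``k_grid`` + attrs."""
        import json

        with h5py.File(path, "w") as f:
            f.create_dataset("fringes", data=self.fringes,
                             chunks=(self.fringes.shape[0], 1, self.fringes.shape[2]),
                             track_times=False)
            f.create_dataset("k_grid", data=self.k_grid, track_times=False)
            acq = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(self.acquisition).items()}
            f.attrs["acquisition"] = json.dumps(acq)
            if self.ground_truth is not None:
                f.attrs["ground_truth"] = json.dumps(
                    _jsonify(self.ground_truth)
                )

    @classmethod
    def load(cls, path) -> "RawScan":
        import json

        with h5py.File(path, "r") as f:
            acq_d = json.loads(f.attrs["acquisition"])
            acq_d["lateral_shape"] = tuple(acq_d["lateral_shape"])
            acq = AcquisitionSpec(**acq_d)
            gt = None
            if "ground_truth" in f.attrs:
                gt = json.loads(f.attrs["ground_truth"])
            return cls(fringes=f["fringes"][...], acquisition=acq, ground_truth=gt)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _system_matrix(phantom: PhantomVolume, acq: AcquisitionSpec) -> tuple:
    """Shared complex response matrix M(k, j) for the relative depth grid.

    M already contains √(μ_b Δz), the round-trip Beer-Lambert attenuation
    from the surface, the rolloff *relative* to the surface depth, and the
    propagation phase for the depth below the surface.  A column with surface
    optical depth ζ₀ then contributes S = Re[rolloff(ζ₀) e^{2ikζ₀} (M g)].
    """
    k = acq.k_grid
    lam = acq.lambda_of_k
    z_rel, mu_t, mu_b, _ = phantom.column_profiles(lam, acq)
    dz_cm = acq.scatterer_spacing_um / _UM_PER_CM
    # one-sided optical thickness from surface to each scatterer (cm⁻¹·cm)
    tau = np.cumsum(mu_t, axis=1) * dz_cm - mu_t * (dz_cm / 2.0)
    z_opt_rel = z_rel * acq.medium_index
    amp = np.sqrt(mu_b * dz_cm) * np.exp(-tau) * acq.rolloff_amplitude(z_opt_rel)
    phase = np.exp(2j * np.outer(k, z_opt_rel * 1e3))  # z in nm
    return z_rel, amp * phase


def simulate_aline(
    phantom: PhantomVolume,
    acq: AcquisitionSpec,
    rng: np.random.Generator,
    surface_um: Optional[float] = None,
) -> np.ndarray:
    """One speckled interferogram S(k) for a single column."""
    z0 = float(np.asarray(phantom.surface_um).flat[0] if surface_um is None
               else surface_um)
    _, M = _system_matrix(phantom, acq)
    n_scat = M.shape[1]
    g = (rng.standard_normal(n_scat) + 1j * rng.standard_normal(n_scat)) / np.sqrt(2.0)
    zeta0 = z0 * acq.medium_index
    p0 = acq.rolloff_amplitude(zeta0) * np.exp(2j * acq.k_grid * zeta0 * 1e3)
    return np.real(p0 * (M @ g))


def simulate_volume(
    phantom: PhantomVolume,
    acq: AcquisitionSpec,
    rng: Optional[np.random.Generator] = None,
) -> RawScan:
    """Raster of speckled A-lines over (x, y); ground truth embedded.

    Deterministic (bit-identical) for a fixed (phantom, acquisition, seed).
    """
    if rng is None:
        rng = np.random.default_rng(acq.rng_seed)
    deepest = (phantom.surface_um.max()
               + phantom.total_thickness_um) * acq.medium_index
    z_range = acq.z_grid_um[-1]
    if deepest > z_range:
        import warnings

        warnings.warn(
            f"phantom extends to {deepest:.0f} μm optical path, beyond the "
            f"unambiguous imaging range {z_range:.0f} μm: deep signal will "
            "fold back (conjugate ambiguity), as in a real FD-OCT system",
            stacklevel=2,
        )
    nx, ny = acq.lateral_shape
    if phantom.surface_um.shape != (nx, ny):
        raise ValueError(
            f"surface profile shape {phantom.surface_um.shape} != lateral "
            f"shape {(nx, ny)}"
        )
    _, M = _system_matrix(phantom, acq)
    n_scat = M.shape[1]
    n_cols = nx * ny
    G = (rng.standard_normal((n_scat, n_cols))
         + 1j * rng.standard_normal((n_scat, n_cols))) / np.sqrt(2.0)
    field = M @ G  # (n_k, n_cols)
    zeta0 = phantom.surface_um.reshape(-1) * acq.medium_index
    p0 = (acq.rolloff_amplitude(zeta0)[None, :]
          * np.exp(2j * np.outer(acq.k_grid, zeta0 * 1e3)))
    fringes = np.real(p0 * field)
    if acq.snr_db is not None:
        sigma = _noise_sigma(phantom, acq)
        fringes = fringes + sigma * rng.standard_normal(fringes.shape)
    from .spectral import default_band_centers

    gt = phantom.ground_truth(
        default_band_centers(acq.lambda_min, acq.lambda_max), acq
    )
    return RawScan(
        fringes=fringes.reshape(acq.n_k, nx, ny),
        acquisition=acq,
        ground_truth=gt,
        phantom=phantom,
    )


def _noise_sigma(phantom: PhantomVolume, acq: AcquisitionSpec) -> float:
    """Per-sample fringe noise std giving ``snr_db`` band intensity at the surface.

    For white fringe noise of std σ, a Gaussian-windowed transform with
    weights w_i yields a flat depth noise floor of variance σ² Σ w_i²; the
    surface signal intensity is taken from the ideal (incoherent) envelope of
    the first band at the shallowest surface point.
    """
    from .spectral import band_windows, default_band_centers

    centers = default_band_centers(acq.lambda_min, acq.lambda_max)
    W = band_windows(acq, centers)
    lam0 = float(centers[len(centers) // 2])
    z_rel, mu_t, mu_b, _ = phantom.column_profiles(np.array([lam0]), acq)
    dz_cm = acq.scatterer_spacing_um / _UM_PER_CM
    zeta_min = float(phantom.surface_um.min()) * acq.medium_index
    surf_int = (mu_b[0, 0] * dz_cm) * acq.rolloff_amplitude(zeta_min) ** 2
    # signal intensity at the surface voxel after the mid-band window
    w = W[len(centers) // 2]
    # coherent peak of one resolution cell ≈ Σw² × (per-scatterer intensity ×
    # number of scatterers inside the band axial PSF)
    sig = surf_int * np.sum(w**2) * _band_cell_scatterers(acq, w)
    noise_var = sig / 10.0 ** (acq.snr_db / 10.0)
    return float(np.sqrt(noise_var / np.sum(w**2)))


def _band_cell_scatterers(acq: AcquisitionSpec, w: np.ndarray) -> float:
    """Effective number of scatterers per band resolution cell."""
    sigma_k = np.sqrt(np.sum(w**2 * (acq.k_grid - np.average(acq.k_grid, weights=w**2)) ** 2)
                      / np.sum(w**2))
    fwhm_z_nm = 2.0 * np.sqrt(np.log(2.0)) / (2.0 * sigma_k)
    return max(fwhm_z_nm * 1e-3 / (acq.scatterer_spacing_um * acq.medium_index), 1.0)


def simulate_ideal_cube(
    phantom: PhantomVolume,
    acq: AcquisitionSpec,
    band_centers: Optional[np.ndarray] = None,
    band_fwhm: float = 20.0,
):
    """Speckle-free mode: the deterministic incoherent band-intensity cube.

    I(band, x, y, z) = μ_b(λ_band) e^{-2 ∫ μ_t dz'} rolloff²(z) on the same
    optical-path depth grid the fringe path produces — obeys the module's
    Beer-Lambert contract exactly (ln I depth slope = −2 μ_t).
    """
    from .spectral import SpectralCube, default_band_centers

    if band_centers is None:
        band_centers = default_band_centers(acq.lambda_min, acq.lambda_max)
    band_centers = np.asarray(band_centers, dtype=float)
    z_grid = acq.z_grid_um  # optical path
    nx, ny = acq.lateral_shape
    if phantom.surface_um.shape != (nx, ny):
        raise ValueError("surface profile shape mismatch")
    z_rel, mu_t, mu_b, _ = phantom.column_profiles(band_centers, acq)
    dz_cm = acq.scatterer_spacing_um / _UM_PER_CM
    tau = np.cumsum(mu_t, axis=1) * dz_cm - mu_t * (dz_cm / 2.0)
    prof = mu_b * np.exp(-2.0 * tau)  # (n_band, n_zrel), per unit μ_b scale
    z_opt_rel = z_rel * acq.medium_index
    intensity = np.zeros((band_centers.size, nx, ny, z_grid.size))
    zeta0 = phantom.surface_um * acq.medium_index
    for ix in range(nx):
        for iy in range(ny):
            z_abs = zeta0[ix, iy] + z_opt_rel
            roll2 = acq.rolloff_amplitude(z_abs) ** 2
            for b in range(band_centers.size):
                intensity[b, ix, iy, :] = np.interp(
                    z_grid, z_abs, prof[b] * roll2, left=0.0, right=0.0
                )
    return SpectralCube(
        intensity=intensity,
        band_centers=band_centers,
        band_fwhm=band_fwhm,
        z_grid=z_grid,
        provenance=["simulate_ideal_cube (speckle-free incoherent envelope)"],
    )
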