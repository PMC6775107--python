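"""Short-time Fourier transform of raw fringes into the 4-D spectral cube.

The acquired interferogram spectrum S(k) of each A-line is multiplied by a
set of Gaussian windows (by default 22 windows whose centers are uniform in
wavelength over 520–720 nm, each 20 nm FWHM in λ, mapped to k-space where the
transform is performed) and Fourier-transformed to depth.  The stored
quantity is magnitude-squared band intensity, so downstream Beer-Lambert
depth slopes are −2 μ_t, and the depth axis is optical path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .forward_sim import AcquisitionSpec, RawScan

__all__ = [
    "SpectralCube",
    "default_band_centers",
    "band_windows",
    "stft_cube",
    "reference_calibrate",
]

DEFAULT_N_BANDS = 22
DEFAULT_BAND_FWHM = 20.0


@dataclass
class SpectralCube:
    """Spectrally resolved OCT intensity I_b(band, x, y, z).

    ``z_grid`` is optical-path depth in μm; ``band_centers`` are vacuum
    wavelengths in nm, strictly increasing; intensity is nonnegative.
    """

    intensity: np.ndarray
    band_centers: np.ndarray
    band_fwhm: float
    z_grid: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        if np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if self.intensity.shape[0] != self.band_centers.size:
            raise ValueError("intensity first axis must match band count")
        if np.any(self.intensity < 0):
            raise ValueError("band intensity must be nonnegative")

    @property
    def n_bands(self) -> int:
        return int(self.band_centers.size)

    @property
    def dz_um(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])

    def band_mean_spectrum(self) -> np.ndarray:
        """Volume-mean intensity per band (diagnostic)."""
        return self.intensity.reshape(self.n_bands, -1).mean(axis=1)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=self.intensity,
                             chunks=(self.n_bands, 1, self.intensity.shape[2],
                                     self.intensity.shape[3]),
                             track_times=False)
            f.create_dataset("band_centers", data=self.band_centers,
                             track_times=False)
            f.create_dataset("z_grid", data=self.z_grid, track_times=False)
            f.attrs["band_fwhm"] = self.band_fwhm
            f.attrs["provenance"] = "\n".join(self.provenance)

    @classmethod
    def load(cls, path) -> "SpectralCube":
        with h5py.File(path, "r") as f:
            return cls(
                intensity=f["intensity"][...],
                band_centers=f["band_centers"][...],
                band_fwhm=float(f.attrs["band_fwhm"]),
                z_grid=f["z_grid"][...],
                provenance=str(f.attrs["provenance"]).splitlines(),
            )


def default_band_centers(
    lambda_min: float = 520.0,
    lambda_max: float = 720.0,
    n_bands: int = DEFAULT_N_BANDS,
    band_fwhm: float = DEFAULT_BAND_FWHM,
) -> np.ndarray:
    """Band centers uniform in λ, inset half a FWHM from the band edges."""
    return np.linspace(lambda_min + band_fwhm / 2.0,
                       lambda_max - band_fwhm / 2.0, n_bands)


def band_psf_fwhm_um(
    band_centers: np.ndarray, band_fwhm: float = DEFAULT_BAND_FWHM
) -> np.ndarray:
    """Axial intensity-PSF FWHM of each band image (optical path, μm).

    A Gaussian k-window of std σ_k gives an intensity PSF of FWHM
    √(ln 2)/σ_k; wider wavelength bands → narrower PSFs and vice versa, the
    spectral–spatial tradeoff.  Used to size the surface guard that keeps
    depth fits clear of the blurred surface step.
    """
    centers = np.asarray(band_centers, dtype=float)
    fwhm_k = 2.0 * np.pi * band_fwhm / centers**2  # nm⁻¹
    sigma_k = fwhm_k / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.sqrt(np.log(2.0)) / sigma_k * 1e-3  # nm → μm


def band_windows(
    acq: AcquisitionSpec,
    band_centers: np.ndarray,
    band_fwhm: float = DEFAULT_BAND_FWHM,
) -> np.ndarray:
    """Gaussian k-space windows, one row per band.

    Each window is centered at k_c = 2π/λ_c with its FWHM mapped from the
    stated wavelength width at that center: Δk = 2π Δλ / λ_c².
    """
    k = acq.k_grid
    centers = np.asarray(band_centers, dtype=float)
    if np.any(centers - band_fwhm / 2.0 < acq.lambda_min) or np.any(
        centers + band_fwhm / 2.0 > acq.lambda_max
    ):
        raise ValueError("band extends beyond the acquired spectrum")
    k_c = 2.0 * np.pi / centers
    fwhm_k = 2.0 * np.pi * band_fwhm / centers**2
    sigma_k = fwhm_k / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((k[None, :] - k_c[:, None]) / sigma_k[:, None]) ** 2)


def stft_cube(
    raw: RawScan,
    band_centers: np.ndarray | None = None,
    band_fwhm: float = DEFAULT_BAND_FWHM,
    z_max_um: float | None = None,
    dtype=np.float64,
    correct_rolloff: bool = True,
) -> SpectralCube:
    """Windowed Fourier transform of the fringes into the spectral cube.

    Band intensities are |FFT(w·S)|² / Σw², making a spectrally white fringe
    read the same in every band before calibration.  ``z_max_um`` optionally
    crops the stored depth range (optical path).  With ``correct_rolloff``
    the known spectrometer sensitivity decay from the acquisition metadata is
    divided out, so depth fits see only the sample's attenuation.
    """
    acq = raw.acquisition
    if band_centers is None:
        band_centers = default_band_centers(acq.lambda_min, acq.lambda_max)
    band_centers = np.asarray(band_centers, dtype=float)
    k = acq.k_grid
    if not np.allclose(np.diff(k), k[1] - k[0], rtol=1e-9):
        raise ValueError("k grid must be uniform (resample before the STFT)")
    W = band_windows(acq, band_centers, band_fwhm)
    z_grid = acq.z_grid_um
    n_z = z_grid.size
    if z_max_um is not None:
        n_z = int(np.searchsorted(z_grid, z_max_um, side="right"))
        z_grid = z_grid[:n_z]
    n_k, nx, ny = raw.fringes.shape
    flat = raw.fringes.reshape(n_k, nx * ny)
    out = np.empty((band_centers.size, nx, ny, n_z), dtype=dtype)
    for b, w in enumerate(W):
        spec = np.fft.fft(flat * w[:, None], axis=0)[:n_z]
        out[b] = (np.abs(spec.T) ** 2 / np.sum(w**2)).reshape(nx, ny, n_z)
    prov = [f"stft_cube: {band_centers.size} bands, fwhm={band_fwhm} nm"]
    if correct_rolloff and acq.rolloff_db_per_mm != 0.0:
        out /= acq.rolloff_amplitude(z_grid)[None, None, None, :] ** 2
        prov.append(f"rolloff corrected ({acq.rolloff_db_per_mm} dB/mm)")
    return SpectralCube(
        intensity=out,
        band_centers=band_centers,
        band_fwhm=band_fwhm,
        z_grid=z_grid,
        provenance=prov,
    )


def reference_calibrate(
    cube: SpectralCube,
    reference: SpectralCube | None = None,
    apply_model: bool = False,
    model_exponent: float = -4.0,
    min_ref_fraction: float = 1e-6,
) -> SpectralCube:
    """Correct the per-band system spectral response using a Rayleigh reference.

    The reference scan images a medium whose backscatter spectrum is known to
    follow λ⁻⁴ (e.g. 80 nm polystyrene beads), so its measured band means are
    the instrument response times that model.  Each band of ``cube`` is
    divided by the reference band mean (response removal; a self-calibrated
    Rayleigh cube becomes spectrally flat).  With ``apply_model=True`` the
    known λ^model_exponent shape is multiplied back in, so the output carries
    the physical reference spectrum; in analytic mode (``reference=None``)
    only that model factor is applied.  Near-zero reference bands are masked
    (set to NaN response → zero intensity, recorded in provenance).
    """
    lam = cube.band_centers
    model = (lam / lam[len(lam) // 2]) ** model_exponent
    if reference is None:
        response = np.ones_like(lam)
        note = "reference_calibrate: analytic mode"
    else:
        if reference.n_bands != cube.n_bands or not np.allclose(
            reference.band_centers, cube.band_centers
        ):
            raise ValueError("reference must cover the same bands")
        ref_band = reference.band_mean_spectrum()
        bad = ref_band <= min_ref_fraction * ref_band.max()
        response = ref_band / np.where(bad, np.nan, 1.0)
        response = response / np.nanmean(response)
        note = f"reference_calibrate: scan reference, {int(bad.sum())} bands masked"
    scale = (model if apply_model else 1.0) / response
    scale = np.where(np.isfinite(scale), scale, 0.0)
    out = cube.intensity * scale[:, None, None, None]
    return SpectralCube(
        intensity=out,
        band_centers=cube.band_centers,
        band_fwhm=cube.band_fwhm,
        z_grid=cube.z_grid,
        provenance=cube.provenance + [note, f"apply_model={apply_model}"],
    )
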