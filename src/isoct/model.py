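"""High-level modelling interface: ``ISOCTModel`` / ``ISOCTResults``.

The spectral inversion is, end to end, a model fitted to data: a raw OCT
volume comes in, and estimates of (μ_t(λ), μ_b(λ), μ_s(λ), μ_a(λ), D, g,
chlorophyll-a density) with per-pixel diagnostics come out.  This module
packages the pipeline in the familiar model/results idiom::

    model = ISOCTModel(scan, config)
    res = model.fit(reference=ref_scan)
    print(res.summary())
    res.save_maps("outdir")

Every stage remains individually accessible through the stage modules
(:mod:`isoct.spectral`, :mod:`isoct.surface`, :mod:`isoct.attenuation`,
:mod:`isoct.inversion`); this class only orchestrates them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import attenuation as _att
from . import inversion as _inv
from . import pigment as _pig
from . import spectral as _sp
from . import surface as _sf
from . import wm_model as _wm
from .config import RunConfig
from .forward_sim import RawScan

__all__ = ["ISOCTModel", "ISOCTResults"]


class ISOCTModel:
    """Inverse spectroscopic OCT model for one raw scan.

    Parameters
    ----------
    data : RawScan or SpectralCube
        The measured (or simulated) volume.  A raw scan is transformed with
        the configured STFT; a spectral cube is used as-is.
    config : RunConfig, optional
        Processing configuration; defaults mirror the standard settings.
    skeleton_mode : bool
        Disable absorption fitting (skeletal scans): the decomposition
        reduces to (c_s, D, L_n) and no chlorophyll map is produced.
    """

    def __init__(
        self,
        data,
        config: Optional[RunConfig] = None,
        skeleton_mode: bool = False,
        manual_surface: Optional[_sf.SurfaceMap] = None,
    ) -> None:
        self.config = config or RunConfig()
        self.skeleton_mode = skeleton_mode
        self.manual_surface = manual_surface
        if isinstance(data, RawScan):
            self.scan: Optional[RawScan] = data
            centers = _sp.default_band_centers(
                data.acquisition.lambda_min, data.acquisition.lambda_max,
                self.config.stft.n_bands, self.config.stft.band_fwhm_nm,
            )
            self.cube = _sp.stft_cube(
                data, centers, self.config.stft.band_fwhm_nm,
                z_max_um=self.config.stft.z_max_um,
            )
        elif isinstance(data, _sp.SpectralCube):
            self.scan = None
            self.cube = data
        else:
            raise TypeError("data must be a RawScan or SpectralCube")
        self._pigment = self._load_pigment()
        self._lookup: Optional[_wm.GLookupTable] = None

    def _load_pigment(self) -> _pig.PigmentSpectrum:
        pc = self.config.pigment
        if pc.spectrum_table is not None:
            return _pig.PigmentSpectrum.from_table(
                pc.spectrum_table, epsilon_peak=pc.epsilon_peak,
                convention=pc.convention,
            )
        return _pig.chlorophyll_a_reference()

    @property
    def lookup(self) -> _wm.GLookupTable:
        """Albedo → g lookup table (built lazily from the lookup config)."""
        if self._lookup is None:
            lc = self.config.lookup
            self._lookup = _wm.build_g_lookup(
                D_grid=np.arange(lc.D_min, lc.D_max + lc.D_step / 2, lc.D_step),
                albedo_grid=np.geomspace(1e-6, 1.0, lc.n_albedo),
                wavelength=lc.wavelength_nm,
                medium_index=self.config.acquisition.medium_index,
                collection_sr=self.config.acquisition.collection_sr,
            )
        return self._lookup

    def detect_surface(self) -> _sf.SurfaceMap:
        sc = self.config.surface
        detected = _sf.detect_surface(
            self.cube, h=sc.h_maxima, min_object_px=sc.min_object_px
        )
        merged = _sf.merge_surfaces(detected, self.manual_surface)
        return _sf.apply_validity_filters(
            merged, self.cube,
            rolloff_db_per_mm=self.config.acquisition.rolloff_db_per_mm,
            rolloff_limit_db=sc.rolloff_limit_db,
            specular_threshold=sc.specular_threshold,
        )

    def calibration(self, reference: Optional[RawScan]) -> np.ndarray | float:
        """Per-band bead-standard calibration from a reference scan.

        The reference's embedded ground truth supplies the known μ_b(λ); the
        scan is processed with the same surface/attenuation/window chain as
        the sample so systematic factors cancel in the ratio.
        """
        if reference is None:
            return 1.0
        ref_model = ISOCTModel(reference, self.config)
        ref_surface = ref_model.detect_surface()
        if reference.ground_truth is None:
            raise ValueError("reference scan carries no known μ_b ground truth")
        known = np.asarray(reference.ground_truth["layers"][0]["mu_b"], dtype=float)
        return _att.calibration_from_reference(
            ref_model.cube, ref_surface, known,
            depth_window_um=self.config.fit.depth_window_um,
            medium_index=self.config.acquisition.medium_index,
        )

    def fit(self, reference: Optional[RawScan] = None) -> "ISOCTResults":
        """Run the full inversion and return the results object."""
        fc = self.config.fit
        surface = self.detect_surface()
        atten = _att.fit_mu_t(
            self.cube, surface, fc.depth_window_um, fc.lateral_kernel,
            medium_index=self.config.acquisition.medium_index,
        )
        scale = self.calibration(reference)
        maps = _inv.build_property_maps(
            self.cube, surface, atten, self.lookup,
            calibration_scale=scale, chl_reference=self._pigment,
            skeleton_mode=self.skeleton_mode,
            depth_window_um=fc.depth_window_um,
            decompose_block=fc.decompose_block,
            alpha_reference_nm=fc.alpha_reference_nm,
            n_starts=fc.n_starts, seed=fc.fit_seed,
            medium_index=self.config.acquisition.medium_index,
        )
        return ISOCTResults(model=self, surface=surface, atten=atten, maps=maps)


@dataclass
class ISOCTResults:
    """Fitted property maps with diagnostics and export helpers."""

    model: ISOCTModel
    surface: _sf.SurfaceMap
    atten: _att.AttenuationMaps
    maps: _inv.PropertyMaps

    @property
    def valid_fraction(self) -> float:
        return float(self.maps.valid.mean())

    def summary(self) -> pd.DataFrame:
        """Median / IQR table of the recovered per-pixel quantities."""
        rows = []
        v = self.maps.valid

        def add(name, unit, arr, mask):
            vals = np.asarray(arr)[mask] if mask.any() else np.array([np.nan])
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                vals = np.array([np.nan])
            rows.append({
                "quantity": name, "unit": unit,
                "median": np.median(vals),
                "iqr_low": np.percentile(vals, 25),
                "iqr_high": np.percentile(vals, 75),
                "n": vals.size,
            })

        lam = self.maps.band_centers
        mid = int(np.argmin(np.abs(lam - 620.0)))
        add(f"mu_t({lam[mid]:.0f} nm)", "cm^-1", self.maps.mu_t[mid], v)
        add(f"mu_b({lam[mid]:.0f} nm)", "cm^-1", self.maps.mu_b[mid], v)
        add(f"mu_s({lam[mid]:.0f} nm)", "cm^-1", self.maps.mu_s[mid], v)
        add("D", "-", self.maps.fractal.D, v)
        add("g", "-", self.maps.fractal.g, self.maps.fractal.g_valid)
        if not self.maps.skeleton_mode:
            add(f"mu_a({lam[-5]:.0f} nm)", "cm^-1", self.maps.mu_a[-5], v)
            add("chl areal density", "ug cm^-2", self.maps.chl_areal, v)
        return pd.DataFrame(rows)

    def histogram(self, quantity: str = "D", bins: int = 50) -> pd.DataFrame:
        """Per-pixel frequency histogram (frequencies sum to 1)."""
        arr = {
            "D": self.maps.fractal.D,
            "g": self.maps.fractal.g,
            "chl": self.maps.chl_areal,
        }[quantity]
        mask = self.maps.fractal.g_valid if quantity == "g" else self.maps.valid
        vals = np.asarray(arr)[mask]
        vals = vals[np.isfinite(vals)]
        counts, edges = np.histogram(vals, bins=bins)
        freq = counts / max(counts.sum(), 1)
        return pd.DataFrame({
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "frequency": freq,
        })

    def save_maps(self, outdir) -> None:
        """Write all maps (32-bit float TIFF + CSV) with provenance."""
        import tifffile

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.model.config.write_beside(out)
        self.surface.save(out / "surface")
        self.atten.save(out / "mu_t")

        def w(name, arr):
            tifffile.imwrite(out / f"{name}.tif",
                             np.asarray(arr, dtype=np.float32))

        w("mu_b_bands", self.maps.mu_b)
        w("mu_s_bands", self.maps.mu_s)
        w("D_map", np.where(self.maps.valid, self.maps.fractal.D, np.nan))
        w("g_map", np.where(self.maps.fractal.g_valid, self.maps.fractal.g, np.nan))
        if not self.maps.skeleton_mode:
            w("mu_a_bands", self.maps.mu_a)
            w("chl_areal_ug_cm2",
              np.where(self.maps.valid, self.maps.chl_areal, np.nan))
        self.summary().to_csv(out / "summary.csv", index=False)
        for q in ("D", "g") + (() if self.maps.skeleton_mode else ("chl",)):
            self.histogram(q).to_csv(out / f"hist_{q}.csv", index=False)
        prov = self.maps.provenance + [
            f"config_hash={self.model.config.config_hash()}",
            f"valid_fraction={self.valid_fraction:.4f}",
        ]
        (out / "provenance.txt").write_text("\n".join(prov) + "\n")
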