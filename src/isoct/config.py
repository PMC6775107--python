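"""Run configuration: one schema-validated file drives simulate and process.

Defaults mirror the standard acquisition and analysis settings: 520–720 nm
band, 22 STFT windows of 20 nm FWHM, a 90 μm attenuation-fit window, and a
−10 dB/mm roll-off.  Every run writes its resolved configuration beside the
outputs so a recovery experiment is a two-command script.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import forward_sim as _fs
from . import wm_model as _wm

__all__ = ["RunConfig", "load_config", "build_acquisition", "build_phantom"]


class AcquisitionConfig(BaseModel):
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

    @field_validator("n_k")
    @classmethod
    def _nk(cls, v):
        if v < 512:
            raise ValueError("n_k must be >= 512")
        return v


class LayerConfig(BaseModel):
    thickness_um: float = Field(gt=0)
    D: float
    Ln_nm: float = Field(gt=0)
    mu_s_600_cm1: Optional[float] = None  # solve A_n for this μ_s(600 nm)
    An: Optional[float] = None
    chl_volumetric_mg_cm3: float = Field(default=0.0, ge=0)
    backscatter_scale: float = 1.0
    kind: Literal["tissue", "skeleton"] = "tissue"


class PhantomConfig(BaseModel):
    layers: list[LayerConfig] = Field(default_factory=list)
    surface_depth_um: float = 200.0
    surface_tilt_um_per_mm: float = 0.0


class StftConfig(BaseModel):
    n_bands: int = 22
    band_fwhm_nm: float = 20.0
    z_max_um: Optional[float] = None


class SurfaceConfig(BaseModel):
    h_maxima: float = 0.2
    min_object_px: int = 32
    rolloff_limit_db: float = float("inf")
    specular_threshold: float = float("inf")


class FitConfig(BaseModel):
    depth_window_um: float = 90.0
    lateral_kernel: int = 3
    decompose_block: int = 8
    n_starts: int = 8
    alpha_reference_nm: float = 620.0
    fit_seed: int = 0


class LookupConfig(BaseModel):
    D_min: float = 1.3
    D_max: float = 5.8
    D_step: float = 0.05
    n_albedo: int = 300
    wavelength_nm: float = 620.0


class PigmentConfig(BaseModel):
    spectrum_table: Optional[str] = None  # two-column fixture; None = packaged
    epsilon_peak: float = 71930.0
    convention: Literal["decadic", "natural"] = "decadic"


class RunConfig(BaseModel):
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    stft: StftConfig = Field(default_factory=StftConfig)
    surface: SurfaceConfig = Field(default_factory=SurfaceConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    lookup: LookupConfig = Field(default_factory=LookupConfig)
    pigment: PigmentConfig = Field(default_factory=PigmentConfig)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]

    def write_beside(self, outdir) -> Path:
        out = Path(outdir) / "resolved_config.yaml"
        out.write_text(self.resolved_yaml())
        return out


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig.model_validate(data)


def build_acquisition(cfg: RunConfig) -> _fs.AcquisitionSpec:
    a = cfg.acquisition
    return _fs.AcquisitionSpec(
        lambda_min=a.lambda_min, lambda_max=a.lambda_max, n_k=a.n_k,
        lateral_shape=tuple(a.lateral_shape), pixel_pitch_um=a.pixel_pitch_um,
        rolloff_db_per_mm=a.rolloff_db_per_mm, snr_db=a.snr_db,
        rng_seed=a.rng_seed, medium_index=a.medium_index,
        collection_sr=a.collection_sr,
        scatterer_spacing_um=a.scatterer_spacing_um,
    )


def build_phantom(cfg: RunConfig) -> _fs.PhantomVolume:
    if not cfg.phantom.layers:
        raise ValueError("phantom config has no layers")
    layers = []
    for lc in cfg.phantom.layers:
        if lc.An is not None:
            wm = _wm.WMParams(An=lc.An, Ln=lc.Ln_nm, D=lc.D)
        elif lc.mu_s_600_cm1 is not None:
            wm = _wm.amplitude_for_mu_s(
                lc.mu_s_600_cm1, lc.Ln_nm, lc.D,
                medium_index=cfg.acquisition.medium_index,
            )
        else:
            raise ValueError("layer needs either An or mu_s_600_cm1")
        layers.append(_fs.LayerSpec(
            thickness_um=lc.thickness_um, wm=wm,
            chl_volumetric=lc.chl_volumetric_mg_cm3,
            backscatter_scale=lc.backscatter_scale, kind=lc.kind,
        ))
    nx, ny = cfg.acquisition.lateral_shape
    x_mm = np.arange(nx)[:, None] * cfg.acquisition.pixel_pitch_um * 1e-3
    surface = (cfg.phantom.surface_depth_um
               + cfg.phantom.surface_tilt_um_per_mm * x_mm * np.ones((1, ny)))
    return _fs.make_phantom(layers, surface)
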