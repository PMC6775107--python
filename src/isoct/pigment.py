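"""Chlorophyll-a absorption: reference spectrum and concentration conversion.

The pipeline attributes all tissue absorption in the 520–720 nm band to
chlorophyll a, whose Q-band absorption peaks near 660 nm.  The fitted
absorption coefficient at the peak is converted to a molar concentration by
the molar extinction coefficient and then to an areal density by integrating
over the attenuation-fit window.

The packaged reference shape is a synthetic analytic stand-in for a measured
chlorophyll-a-in-methanol spectrum: two Gaussian Q-bands centered at 620 and
660 nm (the digitized laboratory tabulation is not redistributable here).
Its metadata records the extinction convention (decadic) and peak value so
that the unit chain is a single source of truth; any tabulated spectrum with
the same two-column layout can be swapped in via the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PigmentSpectrum",
    "chlorophyll_a_reference",
    "chl_volumetric",
    "chl_areal_density",
    "mu_a_from_concentration",
]

#: Molar mass of chlorophyll a (g mol⁻¹).
CHL_A_MOLAR_MASS = 893.5

#: Decadic molar extinction coefficient of chlorophyll a in methanol at the
#: red Q-band peak (M⁻¹ cm⁻¹), Porra's spectrophotometric value.
CHL_A_EPSILON_PEAK = 71930.0

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class PigmentSpectrum:
    """Normalized absorption shape plus the unit metadata to de-normalize it.

    ``mu_a_star`` is max-normalized (peak = 1 within 655–665 nm);
    ``epsilon_peak`` is the decadic molar extinction coefficient at the peak,
    so the natural-log absorption coefficient of a solution at molarity C is
    μ_a(λ) = ln 10 · ε_peak · C · mu_a_star(λ).
    """

    lambda_grid: np.ndarray
    mu_a_star: np.ndarray
    epsilon_peak: float = CHL_A_EPSILON_PEAK
    molar_mass: float = CHL_A_MOLAR_MASS
    convention: str = "decadic"
    source: str = "synthetic two-Gaussian Q-band stand-in (620/660 nm), methanol-like"

    def __post_init__(self) -> None:
        shape = np.asarray(self.mu_a_star, dtype=float)
        if shape.min() < 0 or shape.max() > 1.0 + 1e-12:
            raise ValueError("mu_a_star must lie in [0, 1]")
        lam = np.asarray(self.lambda_grid, dtype=float)
        peak = lam[int(np.argmax(shape))]
        if not (655.0 <= peak <= 665.0):
            raise ValueError(f"red Q-band peak at {peak} nm outside 655–665 nm")

    def shape_at(self, wavelength) -> np.ndarray:
        """Interpolate the normalized shape onto arbitrary wavelengths."""
        return np.interp(np.asarray(wavelength, dtype=float),
                         self.lambda_grid, self.mu_a_star)

    @property
    def peak_wavelength(self) -> float:
        return float(self.lambda_grid[int(np.argmax(self.mu_a_star))])

    def to_table(self, path) -> None:
        """Write the two-column fixture (wavelength nm, normalized shape)."""
        header = (
            f"chlorophyll a absorption shape, max-normalized\n"
            f"source: {self.source}\n"
            f"convention: {self.convention}; epsilon_peak={self.epsilon_peak} 1/M/cm; "
            f"molar_mass={self.molar_mass} g/mol\n"
            "wavelength_nm\tshape"
        )
        np.savetxt(path, np.column_stack([self.lambda_grid, self.mu_a_star]),
                   header=header, fmt="%.6g", delimiter="\t")

    @classmethod
    def from_table(cls, path, **meta) -> "PigmentSpectrum":
        data = np.loadtxt(Path(path))
        shape = data[:, 1] / data[:, 1].max()
        return cls(lambda_grid=data[:, 0], mu_a_star=shape, **meta)


def chlorophyll_a_reference(
    lambda_min: float = 500.0, lambda_max: float = 740.0, n: int = 481
) -> PigmentSpectrum:
    """Packaged chlorophyll-a reference shape (synthetic analytic Q-bands).

    Main red band: Gaussian at 660 nm, σ = 11 nm; secondary band at 620 nm,
    σ = 14 nm, relative amplitude 0.28 — reproducing the characteristic
    in-methanol Q-band morphology with negligible absorption below ~560 nm.
    """
    lam = np.linspace(lambda_min, lambda_max, n)
    shape = (
        np.exp(-0.5 * ((lam - 660.0) / 11.0) ** 2)
        + 0.28 * np.exp(-0.5 * ((lam - 620.0) / 14.0) ** 2)
    )
    return PigmentSpectrum(lambda_grid=lam, mu_a_star=shape / shape.max())


def chl_volumetric(mu_a_at_peak: float, spectrum: PigmentSpectrum):
    """Concentration from the absorption coefficient at the 660 nm peak.

    Returns (molarity in mol L⁻¹, mass concentration in mg cm⁻³).  μ_a is the
    natural-log (Beer-Lambert exponent) coefficient in cm⁻¹; with a decadic
    extinction fixture the conversion is C = μ_a / (ln 10 · ε_peak).
    """
    if mu_a_at_peak < 0:
        raise ValueError("absorption coefficient must be >= 0")
    if spectrum.convention == "decadic":
        molar = mu_a_at_peak / (LN10 * spectrum.epsilon_peak)
    elif spectrum.convention == "natural":
        molar = mu_a_at_peak / spectrum.epsilon_peak
    else:
        raise ValueError(f"unknown extinction convention {spectrum.convention!r}")
    # mol/L → mg/cm³: × molar_mass [g/mol] × 1000 [mg/g] / 1000 [cm³/L]
    mass = molar * spectrum.molar_mass
    return molar, mass


def chl_areal_density(volumetric_mg_cm3, thickness_um: float = 90.0):
    """Areal density (μg cm⁻²) from a volumetric concentration (mg cm⁻³).

    Constant concentration is assumed over the fit window, so the integral is
    a product: areal = volumetric × thickness.
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be > 0")
    vol = np.asarray(volumetric_mg_cm3, dtype=float)
    out = vol * 1000.0 * (thickness_um * 1e-4)  # μg/cm³ × cm
    return out if out.ndim else float(out)


def mu_a_from_concentration(
    concentration_mg_cm3: float, lambda_grid, spectrum: PigmentSpectrum
) -> np.ndarray:
    """Forward map: chlorophyll-a mass concentration → μ_a(λ) in cm⁻¹.

    Exact inverse of :func:`chl_volumetric` at the peak wavelength; used by
    the simulator so forward/inverse closure is a package invariant.
    """
    if concentration_mg_cm3 < 0:
        raise ValueError("concentration must be >= 0")
    molar = concentration_mg_cm3 / spectrum.molar_mass  # mol/L
    if spectrum.convention == "decadic":
        peak = LN10 * spectrum.epsilon_peak * molar
    else:
        peak = spectrum.epsilon_peak * molar
    return peak * spectrum.shape_at(lambda_grid)
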