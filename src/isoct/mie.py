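"""Mie theory for homogeneous spheres: the cross-physics standard.

Used to validate the attenuation fitter against polystyrene microsphere
suspensions with known μ_t, exactly the way bead standards validate a real
instrument.  The partial-wave series follows Bohren & Huffman: logarithmic
derivative by downward recurrence, Riccati-Bessel functions by upward
recurrence.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["mie_coefficients", "mie_efficiencies", "mie_mu_t",
           "polystyrene_index", "rayleigh_cross_section"]


def polystyrene_index(wavelength_nm: float) -> float:
    """Polystyrene refractive index by a Cauchy dispersion fit.

    n(λ) = 1.5725 + 0.0031080/λ² + 0.00034779/λ⁴ with λ in μm — the standard
    visible-range polystyrene dispersion used for bead standards
    (n ≈ 1.59 at 590 nm).
    """
    lam_um = wavelength_nm / 1000.0
    return 1.5725 + 0.0031080 / lam_um**2 + 0.00034779 / lam_um**4


def mie_coefficients(x: float, m: complex, n_terms: int | None = None):
    """Mie coefficients a_n, b_n for size parameter x and relative index m."""
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if n_terms is None:
        n_terms = int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2)) + 5
    n = np.arange(1, n_terms + 1)

    # logarithmic derivative D_n(mx), downward recurrence
    mx = m * x
    n_start = n_terms + int(np.ceil(max(np.abs(mx), n_terms) ** 0.5)) + 16
    Dn = np.zeros(n_start + 1, dtype=complex)
    for k in range(n_start, 0, -1):
        Dn[k - 1] = k / mx - 1.0 / (Dn[k] + k / mx)
    Dn = Dn[1 : n_terms + 1]

    # Riccati-Bessel ψ_n(x), χ_n(x), upward recurrence
    psi = np.zeros(n_terms)
    chi = np.zeros(n_terms)
    psi_m1, psi0 = np.cos(x), np.sin(x)  # ψ_{-1}, ψ_0
    chi_m1, chi0 = -np.sin(x), np.cos(x)
    psi_prev, psi_cur = psi_m1, psi0
    chi_prev, chi_cur = chi_m1, chi0
    for k in range(1, n_terms + 1):
        psi_next = (2.0 * k - 1.0) / x * psi_cur - psi_prev
        chi_next = (2.0 * k - 1.0) / x * chi_cur - chi_prev
        psi[k - 1], chi[k - 1] = psi_next, chi_next
        psi_prev, psi_cur = psi_cur, psi_next
        chi_prev, chi_cur = chi_cur, chi_next
    xi = psi - 1j * chi
    psi_nm1 = np.concatenate(([psi0], psi[:-1]))
    xi_nm1 = np.concatenate(([psi0 - 1j * chi0], xi[:-1]))

    a = ((Dn / m + n / x) * psi - psi_nm1) / ((Dn / m + n / x) * xi - xi_nm1)
    b = ((Dn * m + n / x) * psi - psi_nm1) / ((Dn * m + n / x) * xi - xi_nm1)
    return a, b


def mie_efficiencies(
    diameter_nm: float,
    n_sphere: complex,
    n_medium: float,
    wavelength_nm: float,
):
    """(Q_ext, Q_sca) extinction/scattering efficiencies of one sphere."""
    x = np.pi * diameter_nm * n_medium / wavelength_nm
    m = n_sphere / n_medium
    a, b = mie_coefficients(x, m)
    n = np.arange(1, a.size + 1)
    qext = 2.0 / x**2 * np.sum((2 * n + 1) * (a.real + b.real))
    qsca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    return float(qext), float(qsca)


def rayleigh_cross_section(
    diameter_nm: float, n_sphere: float, n_medium: float, wavelength_nm: float
) -> float:
    """Rayleigh-limit scattering cross-section of a small sphere (cm²).

    C_sca = (2/3) π⁵ d⁶ / λ_m⁴ · |(m²−1)/(m²+2)|² with λ_m the in-medium
    wavelength — the closed form the Mie series must approach for d ≪ λ.
    """
    lam_m = wavelength_nm / n_medium
    m = n_sphere / n_medium
    lorentz = (m**2 - 1.0) / (m**2 + 2.0)
    c_nm2 = (2.0 / 3.0) * np.pi**5 * diameter_nm**6 / lam_m**4 * abs(lorentz) ** 2
    return c_nm2 * 1e-14  # nm² → cm²


def mie_mu_t(
    sphere_diameter_nm: float,
    n_sphere: complex | None,
    n_medium: float,
    wavelength_nm,
    volume_fraction: float,
) -> float | np.ndarray:
    """Suspension attenuation coefficient μ_t (cm⁻¹) from Mie theory.

    μ_t = number density × extinction cross-section, valid in the
    independent-scattering regime (volume fraction ≪ 1; a warning is issued
    above 5 %).  Pass ``n_sphere=None`` to use the packaged polystyrene
    dispersion.  Linear in volume fraction.
    """
    if volume_fraction > 0.05:
        warnings.warn(
            f"volume fraction {volume_fraction:.3f} > 0.05: dependent scattering "
            "may invalidate the independent-scattering assumption",
            stacklevel=2,
        )
    lam = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    out = np.empty_like(lam)
    v_sphere_cm3 = (np.pi / 6.0) * (sphere_diameter_nm * 1e-7) ** 3
    rho_n = volume_fraction / v_sphere_cm3  # spheres per cm³
    area_cm2 = np.pi * (sphere_diameter_nm * 1e-7 / 2.0) ** 2
    for i, wl in enumerate(lam):
        ns = polystyrene_index(wl) if n_sphere is None else n_sphere
        qext, _ = mie_efficiencies(sphere_diameter_nm, ns, n_medium, wl)
        out[i] = rho_n * qext * area_cm2
    return out if out.size > 1 else float(out[0])
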