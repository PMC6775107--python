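"""Whittle-Matérn model: autocorrelation, spectrum, phase function, μ_s, lookup."""

import numpy as np
import pytest
from scipy import integrate

from isoct.wm_model import (
    DivergenceError,
    GLookupTable,
    WMParams,
    anisotropy_g,
    bn_autocorr,
    build_g_lookup,
    mu_b_spectrum_model,
    mu_s_shape_star,
    mu_s_spectrum,
    mub_exponent,
    optical_spectra,
    phase_function,
    wm_power_spectrum,
)


class TestAutocorrelation:
    def test_d4_is_exact_exponential(self):
        # K_{1/2} closed form turns the model into a pure exponential
        p = WMParams(An=1.0, Ln=100.0, D=4.0)
        r = np.array([50.0, 100.0, 250.0])
        ratio = bn_autocorr(p, r) / bn_autocorr(p, 0.0)
        np.testing.assert_allclose(ratio, np.exp(-r / p.Ln), rtol=1e-9)
        assert abs(bn_autocorr(p, 100.0) / bn_autocorr(p, 0.0) - 0.36787944117) < 1e-9

    @pytest.mark.parametrize("D", [2.5, 3.0])
    def test_origin_diverges_for_mass_fractal(self, D):
        with pytest.raises(DivergenceError):
            bn_autocorr(WMParams(An=1.0, Ln=100.0, D=D), 0.0)

    def test_near_logarithmic_growth_just_above_d3(self):
        # K_0-like small-argument behavior: the value keeps growing as r → 0
        p = WMParams(An=1.0, Ln=100.0, D=3.0001)
        vals = bn_autocorr(p, np.array([1e-1, 1e-3, 1e-5, 1e-7]))
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > vals[0] + 10.0

    def test_high_precision_bessel_oracle(self):
        # frozen from a 20-digit arbitrary-precision evaluation (sympy):
        # (r/L)^{-1/4} K_{-1/4}(r/L) at r = L = 100 nm
        p = WMParams(An=1.0, Ln=100.0, D=2.5)
        assert abs(bn_autocorr(p, 100.0) - 0.43073977444858552) < 1e-12

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            bn_autocorr(WMParams(An=1.0, Ln=100.0, D=4.0), -1.0)

    def test_large_d_approaches_gaussian(self):
        # D = 50: correlation with a fitted Gaussian over the decay range
        p = WMParams(An=1.0, Ln=100.0, D=50.0)
        r = np.linspace(0.0, 3000.0, 200)
        B = bn_autocorr(p, r)
        B = B / B[0]
        keep = B > 1e-3
        coef = np.polyfit(r[keep] ** 2, np.log(B[keep]), 1)
        gauss = np.exp(coef[1] + coef[0] * r[keep] ** 2)
        corr = np.corrcoef(B[keep], gauss)[0, 1]
        assert corr > 0.999


class TestPowerSpectrum:
    def test_characteristic_frequency_ratio(self):
        p = WMParams(An=1.0, Ln=100.0, D=3.0)
        ratio = wm_power_spectrum(p, 1.0 / p.Ln) / wm_power_spectrum(p, 0.0)
        assert abs(ratio - 2.0 ** (-1.5)) < 1e-12
        assert abs(ratio - 0.353553) < 1e-6

    @pytest.mark.parametrize("D", [1.5, 2.5, 4.0])
    def test_monotone_nonincreasing(self, D):
        p = WMParams(An=2.0, Ln=300.0, D=D)
        q = np.geomspace(1e-5, 1.0, 200)
        vals = wm_power_spectrum(p, q)
        assert np.all(np.diff(vals) <= 0)
        assert wm_power_spectrum(p, 0.0) >= vals.max()

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            wm_power_spectrum(WMParams(An=1.0, Ln=100.0, D=3.0), -0.1)

    @pytest.mark.parametrize("D", [2.5, 3.5, 4.5])
    def test_fourier_transform_of_autocorrelation(self, D):
        # Φ(q) must be the 3-D Fourier transform of B_n:
        # Φ(q) = (1/2π²q) ∫ B(r) r sin(qr) dr, evaluated by fine radial
        # quadrature and compared across q ∈ [1e-4, 1e-1] nm⁻¹.
        p = WMParams(An=1.3, Ln=100.0, D=D)
        r = np.linspace(1e-3, 20000.0, 200001)
        B = bn_autocorr(p, r)
        for q in [1e-4, 1e-3, 1e-2, 1e-1]:
            num = np.trapezoid(B * r * np.sin(q * r), r) / (2 * np.pi**2 * q)
            assert abs(num / wm_power_spectrum(p, q) - 1.0) < 0.01


class TestPhaseFunction:
    def test_unit_normalization(self):
        for D, Ln in [(1.5, 50.0), (2.5, 500.0), (3.0, 1000.0), (5.0, 2000.0)]:
            pf = phase_function(WMParams(An=1.0, Ln=Ln, D=D), 600.0)
            assert abs(pf.solid_angle_integral() - 1.0) < 1e-6
            assert np.all(pf.p >= 0)

    def test_isotropic_limit(self):
        # kL_n = 1e-3: the accessible q range sees a constant spectrum
        k = 2 * np.pi * 1.35 / 600.0
        p = WMParams(An=1.0, Ln=1e-3 / k, D=3.0)
        pf = phase_function(p, 600.0)
        assert abs(pf.mean_cosine()) < 1e-3
        assert abs(anisotropy_g(p, 600.0)) < 1e-3

    def test_d3_equals_henyey_greenstein(self):
        # the D = 3 case must coincide with HG after matching g
        p = WMParams(An=1.0, Ln=300.0, D=3.0)
        g = anisotropy_g(p, 600.0)
        pf = phase_function(p, 600.0)
        hg = (1 - g**2) / (4 * np.pi) * (1 + g**2 - 2 * g * np.cos(pf.theta_grid)) ** -1.5
        assert np.abs(pf.p - hg).max() < 1e-6

    def test_forward_lobe_grows_with_anisotropy(self):
        lam, ln = 600.0, 10.0 / (2 * np.pi * 1.35 / 600.0)  # kL_n = 10
        lo = phase_function(WMParams(An=1.0, Ln=ln, D=3.0), lam)
        hi = phase_function(WMParams(An=1.0, Ln=ln, D=5.0), lam)

        def lobe(pf):
            m = pf.theta_grid < np.deg2rad(10.0)
            return integrate.simpson(
                (pf.p * 2 * np.pi * np.sin(pf.theta_grid))[m], x=pf.theta_grid[m]
            )

        # larger D at fixed kL_n → higher g → more forward-lobe mass
        assert anisotropy_g(WMParams(An=1, Ln=ln, D=5.0), lam) > anisotropy_g(
            WMParams(An=1, Ln=ln, D=3.0), lam
        )
        assert lobe(hi) > lobe(lo)


class TestAnisotropy:
    def test_monotone_in_correlation_length(self):
        gs = [anisotropy_g(WMParams(An=1.0, Ln=L, D=3.0), 600.0, method="closed")
              for L in np.geomspace(10.0, 2000.0, 12)]
        assert np.all(np.diff(gs) >= 0)
        assert all(-1 < g < 1 for g in gs)

    def test_quadrature_matches_closed_form(self):
        for D, Ln in [(2.0, 200.0), (3.3, 700.0), (5.5, 100.0)]:
            p = WMParams(An=1.0, Ln=Ln, D=D)
            assert abs(anisotropy_g(p, 600.0) - anisotropy_g(p, 600.0, method="closed")) < 1e-7

    def test_hg_reproduction_at_g09(self):
        # bisect kL_n (via L_n) so that g = 0.9, then HG(g=0.9) must equal p(θ)
        from scipy.optimize import brentq

        f = lambda L: anisotropy_g(WMParams(An=1, Ln=L, D=3.0), 600.0, method="closed") - 0.9
        L9 = brentq(f, 100.0, 5000.0, xtol=1e-9)
        pf = phase_function(WMParams(An=1.0, Ln=L9, D=3.0), 600.0)
        g = 0.9
        hg = (1 - g**2) / (4 * np.pi) * (1 + g**2 - 2 * g * np.cos(pf.theta_grid)) ** -1.5
        assert np.abs(pf.p - hg).max() < 1e-6


class TestScatteringCoefficient:
    def test_linear_in_amplitude(self):
        lam = np.linspace(520.0, 720.0, 5)
        a = mu_s_spectrum(WMParams(An=1.0, Ln=500.0, D=3.0), lam, method="closed")
        b = mu_s_spectrum(WMParams(An=2.0, Ln=500.0, D=3.0), lam, method="closed")
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    @pytest.mark.parametrize("D", [2.0, 3.0, 4.0, 5.0])
    @pytest.mark.parametrize("Ln", [50.0, 1000.0])
    def test_smooth_monotone_over_band(self, D, Ln):
        # no chlorophyll-like peak: the scattering spectrum is monotone in λ,
        # which is what makes the absorption split identifiable
        lam = np.linspace(520.0, 720.0, 41)
        mu = mu_s_spectrum(WMParams(An=1.0, Ln=Ln, D=D), lam, method="closed")
        d = np.diff(mu)
        assert np.all(d < 0) or np.all(d > 0)

    def test_quadrature_matches_closed_form(self):
        lam = np.array([520.0, 620.0, 720.0])
        for D in (2.2, 3.7, 5.1):
            p = WMParams(An=1e-4, Ln=800.0, D=D)
            q = mu_s_spectrum(p, lam, method="quad")
            c = mu_s_spectrum(p, lam, method="closed")
            np.testing.assert_allclose(q, c, rtol=1e-8)

    def test_depends_on_shape_parameter(self):
        vals = [mu_s_spectrum(WMParams(An=1.0, Ln=300.0, D=D), 600.0, method="closed")
                for D in (2.0, 3.0, 4.0)]
        assert np.ptp(vals) / max(vals) > 0.1

    def test_normalized_shape_agrees(self):
        lam = np.linspace(520.0, 720.0, 22)
        p = WMParams(An=3e-5, Ln=700.0, D=2.7)
        full = mu_s_spectrum(p, lam, method="closed")
        star = mu_s_shape_star(lam, 2.7, 700.0)
        np.testing.assert_allclose(full / full.max(), star, rtol=1e-10)


class TestSpectralExponent:
    @pytest.mark.parametrize("D,expo", [(4.0, 0.0), (3.0, -0.5), (1.5, -1.25)])
    def test_exponent_values(self, D, expo):
        assert mub_exponent(D) == pytest.approx(expo, abs=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mub_exponent(0.5)

    @pytest.mark.parametrize("D", [2.0, 3.0, 4.0, 5.0])
    def test_model_amplitude_spectrum_slope(self, D):
        # √μ_b(λ) ∝ λ^{D/2-2} for L_n ≫ λ
        lam = np.linspace(520.0, 720.0, 22)
        mu_b = mu_b_spectrum_model(WMParams(An=1.0, Ln=20000.0, D=D), lam)
        slope = np.polyfit(np.log(lam), np.log(np.sqrt(mu_b)), 1)[0]
        assert abs(slope - mub_exponent(D)) < 0.05


class TestOpticalSpectraInvariants:
    def test_reduced_scattering_identity(self):
        spec = optical_spectra(WMParams(An=1e-4, Ln=700.0, D=2.8),
                               np.linspace(520, 720, 8))
        np.testing.assert_allclose(spec.mu_s_prime, spec.mu_s * (1 - spec.g),
                                   rtol=1e-12)
        assert np.all(spec.albedo > 0)
        assert np.all((spec.g >= 0) & (spec.g < 1))


class TestGLookup:
    def test_roundtrip_self_consistency(self, g_lookup):
        # compute (α, g) directly for D=3 at g ≈ 0.8, then look g back up
        from scipy.optimize import brentq

        f = lambda L: anisotropy_g(WMParams(An=1, Ln=L, D=3.0),
                                   g_lookup.wavelength, method="closed") - 0.8
        L8 = brentq(f, 50.0, 5000.0)
        p = WMParams(An=1.0, Ln=L8, D=3.0)
        alpha = (mu_b_spectrum_model(p, g_lookup.wavelength)
                 / mu_s_spectrum(p, g_lookup.wavelength, method="closed"))
        g, ok = g_lookup.lookup(alpha, 3.0)
        assert ok
        assert abs(float(g) - 0.8) < 0.01

    def test_monotone_in_albedo(self, g_lookup):
        for i in range(0, g_lookup.D_grid.size, 7):
            row = g_lookup.g[i]
            vals = row[np.isfinite(row)]
            if vals.size > 3:
                d = np.diff(vals)
                assert np.all(d <= 1e-12) or np.all(d >= -1e-12)

    def test_out_of_support_masked(self, g_lookup):
        g, ok = g_lookup.lookup(np.array([1e3, 1e-12]), np.array([3.0, 3.0]))
        assert not ok.any()
        assert np.all(np.isnan(g))

    def test_grids_must_increase(self):
        with pytest.raises(ValueError):
            build_g_lookup(D_grid=np.array([3.0, 2.0]),
                           albedo_grid=np.array([0.1, 0.2]))

    def test_serialization_roundtrip(self, g_lookup, tmp_path):
        path = tmp_path / "lookup.h5"
        g_lookup.save(path)
        back = GLookupTable.load(path)
        np.testing.assert_array_equal(back.g, g_lookup.g)
        np.testing.assert_array_equal(back.D_grid, g_lookup.D_grid)
        assert back.wavelength == g_lookup.wavelength
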