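"""Curve fitting, tangent modulus, nonlinearity parameter, and maps."""

import numpy as np
import pytest

from coce.elasticity import (
    PressureWindow,
    SmoothingConfig,
    extrapolate_zero_stress,
    fit_stress_strain,
    map_elastograms,
    modulus_vs_stress,
    nonlinearity_parameter,
    tangent_modulus,
)
from coce.stress import StressStrainCurve

BACKENDS = ["quadratic", "spline"]


def _curve(eps, sig, **kw):
    defaults = dict(z0=0, x0=0, wz=8, wx=4, z_center_um=0.0, x_center_um=0.0)
    defaults.update(kw)
    return StressStrainCurve(strain=eps, stress_kPa=sig, **defaults)


def _quad_sigma(eps, e0, beta):
    return e0 * (eps + beta * eps**2)


class TestFitStressStrain:
    @pytest.mark.parametrize("backend", BACKENDS)
    def test_linear_samples_fit_exactly(self, backend):
        eps = np.linspace(0, 0.02, 30)
        law = fit_stress_strain(_curve(eps, 100 * eps), SmoothingConfig(backend))
        assert law.usable
        grid = np.linspace(0, 0.02, 50)
        assert np.allclose(law.modulus(grid), 100.0, rtol=1e-6)
        assert law.residual_rms_kPa < 1e-8

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_quadratic_derivative_at_one_percent(self, backend):
        """sigma = 50*(eps + 10*eps^2): tangent at eps=0.01 is 60 kPa."""
        eps = np.linspace(0, 0.03, 40)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 50, 10)),
                                SmoothingConfig(backend))
        assert float(law.modulus(0.01)) == pytest.approx(60.0, rel=0.01)

    def test_repeated_strain_point_deduplicated(self):
        eps = np.array([0, 0.001, 0.002, 0.002, 0.003, 0.004, 0.005, 0.006])
        sig = 100 * eps
        law = fit_stress_strain(_curve(eps, sig))
        assert law.usable

    def test_sigma_zero_at_origin(self):
        eps = np.linspace(0, 0.03, 40)
        for backend in BACKENDS:
            law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 80, 5)),
                                    SmoothingConfig(backend))
            assert abs(float(law.sigma(0.0))) < 1e-9

    def test_unusable_curve_propagates(self):
        c = _curve(np.zeros(3), np.zeros(3), usable=False, note="too short")
        law = fit_stress_strain(c)
        assert not law.usable

    def test_noisy_garbage_rejected_by_residual(self):
        rng = np.random.default_rng(0)
        eps = np.linspace(0, 0.02, 30)
        sig = rng.uniform(0, 2.0, 30)  # uncorrelated stress: no law fits
        law = fit_stress_strain(_curve(eps, sig))
        assert not law.usable

    def test_negative_beta_retained(self):
        """A softening curve fits with beta < 0; not clipped to zero."""
        eps = np.linspace(0, 0.01, 30)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 100, -3)),
                                SmoothingConfig("quadratic"))
        assert law.usable
        assert float(law.modulus(0.01)) < float(law.modulus(0.0))


class TestTangentModulus:
    def test_linear_law_any_window(self):
        eps = np.linspace(0, 0.03, 40)
        law = fit_stress_strain(_curve(eps, 100 * eps))
        for window in [PressureWindow(0.5, 0.5), PressureWindow(2.0, 0.3)]:
            assert tangent_modulus(law, window) == pytest.approx(100.0, rel=1e-6)

    def test_initial_modulus_at_zero_window(self):
        eps = np.linspace(0, 0.05, 60)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 50, 10)))
        assert tangent_modulus(law, PressureWindow(0.0, 1e-6)) == pytest.approx(50.0, rel=0.01)

    def test_tangent_at_derived_point(self):
        """Window shrunk onto 0.55 kPa gives the 60 kPa tangent."""
        eps = np.linspace(0, 0.05, 60)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 50, 10)))
        assert tangent_modulus(law, PressureWindow(0.55, 1e-6)) == pytest.approx(60.0, rel=0.01)

    def test_unreached_window_is_nan(self):
        eps = np.linspace(0, 0.01, 20)
        law = fit_stress_strain(_curve(eps, 100 * eps))  # max stress 1 kPa
        assert np.isnan(tangent_modulus(law, PressureWindow(5.0, 0.5)))


class TestModulusVsStress:
    def test_constant_for_linear_law(self):
        eps = np.linspace(0, 0.03, 40)
        law = fit_stress_strain(_curve(eps, 100 * eps))
        _, E = modulus_vs_stress(law)
        assert np.allclose(E, 100.0, rtol=1e-6)

    def test_quadratic_law_analytic_value(self):
        """E(sigma) = E0*sqrt(1+4*beta*sigma/E0): 60 kPa at 0.55 kPa."""
        eps = np.linspace(0, 0.05, 60)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 50, 10)))
        sig, E = modulus_vs_stress(law, 200)
        at = np.interp(0.55, sig, E)
        assert at == pytest.approx(50 * np.sqrt(1.44), rel=0.01)
        assert np.all(np.diff(E) > 0)  # stiffening is monotone in stress


class TestNonlinearityParameter:
    def test_linear_law_beta_zero(self):
        eps = np.linspace(0, 0.03, 40)
        law = fit_stress_strain(_curve(eps, 100 * eps))
        beta = nonlinearity_parameter(modulus_vs_stress(law), PressureWindow(0.5, 0.5))
        assert abs(beta) < 1e-6

    def test_beta_at_zero_stress(self):
        eps = np.linspace(0, 0.05, 80)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 50, 10)))
        beta = nonlinearity_parameter(modulus_vs_stress(law, 400), PressureWindow(0.05, 0.05))
        assert beta == pytest.approx(10.0, rel=0.02)

    def test_beta_transform_at_finite_stress(self):
        """At the stress where eps=1 %, beta(sigma0) = 10/1.2."""
        eps = np.linspace(0, 0.05, 80)
        law = fit_stress_strain(_curve(eps, _quad_sigma(eps, 50, 10)))
        sigma0 = 0.55
        beta = nonlinearity_parameter(modulus_vs_stress(law, 400),
                                      PressureWindow(sigma0, 0.02))
        assert beta == pytest.approx(10 / 1.2, rel=0.02)

    def test_widening_cap_returns_nan(self):
        sig = np.array([0.0, 0.1])
        E = np.array([50.0, 51.0])
        assert np.isnan(nonlinearity_parameter((sig, E), PressureWindow(5.0, 0.01)))


class TestExtrapolateZeroStress:
    @pytest.mark.parametrize("e0, beta", [(25, 1), (80, 8), (350, 40)])
    def test_inverts_the_standardization_transform(self, e0, beta):
        from coce.phantom import solve_layer_strain

        sigma0 = 0.5
        eps0 = solve_layer_strain(sigma0, e0, beta)
        E_s = e0 * (1 + 2 * beta * eps0)
        beta_s = beta / (1 + 2 * beta * eps0)
        e0_back, beta_back = extrapolate_zero_stress(E_s, beta_s, sigma0)
        assert e0_back == pytest.approx(e0, rel=1e-9)
        assert beta_back == pytest.approx(beta, rel=1e-9)

    def test_inconsistent_inputs_are_nan(self):
        e0, beta = extrapolate_zero_stress(10.0, 100.0, 5.0)
        assert np.isnan(e0) and np.isnan(beta)


class TestMaps:
    def test_mean_modulus_increases_with_pressure(self, homogeneous_curves):
        """Maps at 1/2/4 kPa of a stiffening phantom have increasing mean E."""
        means = []
        for sigma0 in (1.0, 2.0, 4.0):
            pair = map_elastograms(homogeneous_curves, PressureWindow(sigma0, 0.5),
                                   (128, 96))
            means.append(np.nanmean(pair.E_map[pair.mask]))
        assert means[0] < means[1] < means[2]

    def test_window_beyond_max_pressure_fully_masked(self, homogeneous_curves):
        pair = map_elastograms(homogeneous_curves, PressureWindow(50.0, 0.5), (128, 96))
        assert not pair.mask.any()

    def test_masked_pixels_are_nan_not_zero(self, homogeneous_curves):
        pair = map_elastograms(homogeneous_curves, PressureWindow(1.0, 0.5), (128, 96))
        assert np.all(np.isnan(pair.E_map[~pair.mask]))
        assert np.all(pair.E_map[pair.mask] > 0)
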