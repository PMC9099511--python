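"""Phantom generator: constitutive inversion, ground truth, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coce
from coce.phantom import (
    PhantomSpec,
    make_ground_truth,
    render_series,
    seven_region_spec,
    solve_layer_strain,
)


class TestSolveLayerStrain:
    @pytest.mark.parametrize(
        "sigma, e0, beta, expected",
        [
            (1.0, 100.0, 0.0, 0.01),  # linear limit
            (0.0, 55.0, 7.0, 0.0),  # zero load
            (1.0, 100.0, 5.0, (-1 + np.sqrt(1 + 4 * 5 * 0.01)) / (2 * 5)),
        ],
    )
    def test_known_roots(self, sigma, e0, beta, expected):
        assert solve_layer_strain(sigma, e0, beta) == pytest.approx(expected, rel=1e-12)

    def test_derived_root_satisfies_forward_law(self):
        eps = solve_layer_strain(1.0, 100.0, 5.0)
        assert eps == pytest.approx(0.0095445, abs=5e-7)
        assert 100.0 * (eps + 5.0 * eps**2) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sigma=-0.1, E0=100.0, beta=0.0),
            dict(sigma=1.0, E0=0.0, beta=0.0),
            dict(sigma=1.0, E0=100.0, beta=-1.0),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            solve_layer_strain(kwargs["sigma"], kwargs["E0"], kwargs["beta"])

    @settings(max_examples=200, derandomize=True)
    @given(
        sigma=st.floats(0.0, 10.0),
        e0=st.floats(20.0, 1000.0),
        beta=st.floats(0.0, 50.0),
    )
    def test_roundtrip_property(self, sigma, e0, beta):
        """Forward evaluation of the root recovers sigma to 1e-10 relative."""
        eps = solve_layer_strain(sigma, e0, beta)
        back = e0 * (eps + beta * eps**2)
        assert back == pytest.approx(sigma, rel=1e-10, abs=1e-12)


class TestGroundTruth:
    def test_silicone_is_a_linear_sensor(self):
        spec = seven_region_spec(n_frames=40, max_pressure_kPa=2.0, n_z=128, n_x=64)
        gt = make_ground_truth(spec)
        sil = spec.silicone_px
        # silicone cumulative strain exactly sigma / E_sil at every frame
        expected = gt.stress / spec.E_sil_kPa
        assert np.allclose(gt.cumulative[:, :sil, :], expected[:, None, :])
        assert gt.cumulative[-1, 0, 0] == pytest.approx(0.02)

    def test_stress_depth_independent_and_strain_monotone(self):
        spec = seven_region_spec(n_frames=25, max_pressure_kPa=2.0, n_z=128, n_x=64)
        gt = make_ground_truth(spec)
        assert gt.stress.shape == (25, 64)
        assert np.all(np.diff(gt.cumulative, axis=0) >= -1e-15)

    def test_stiffening_reduces_strain(self):
        """Equal E0, beta=10 vs beta=0: the stiffening column strains less."""
        sil = PhantomSpec(n_z=64, n_x=8).silicone_px
        region = np.zeros((64 - sil, 8), dtype=int)
        region[:, 4:] = 1
        spec = PhantomSpec(
            n_z=64,
            n_x=8,
            region_map=region,
            class_params={0: (60.0, 0.0), 1: (60.0, 10.0)},
            pressure_schedule=np.linspace(0, 2.0, 10),
        )
        gt = make_ground_truth(spec)
        soft = gt.cumulative[1:, sil + 2, 0]
        stiff = gt.cumulative[1:, sil + 2, 6]
        assert np.all(stiff < soft)

    def test_quadratic_forward_point(self):
        """E0=50, beta=10 under 0.55 kPa strains by 1%."""
        eps = solve_layer_strain(0.55, 50.0, 10.0)
        assert eps == pytest.approx(0.01, rel=1e-12)

    def test_excessive_schedule_refused(self):
        spec = seven_region_spec(n_frames=10, max_pressure_kPa=2.0, n_z=128, n_x=64)
        spec.class_params[0] = (2.0, 0.0)  # 2 kPa on 2 kPa modulus: 100 % strain
        with pytest.raises(ValueError, match="cumulative strain"):
            make_ground_truth(spec)


class TestSpecValidation:
    def test_schedule_must_be_non_decreasing(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            PhantomSpec(n_z=64, n_x=8, pressure_schedule=np.array([0.0, 1.0, 0.5]))

    def test_labels_must_have_params(self):
        sil = PhantomSpec(n_z=64, n_x=8).silicone_px
        region = np.ones((64 - sil, 8), dtype=int)
        with pytest.raises(ValueError, match="absent from class_params"):
            PhantomSpec(n_z=64, n_x=8, region_map=region, class_params={0: (50.0, 1.0)})

    def test_scan_geometry_defaults(self):
        """Default scan format: 256 x 256 pixels spanning 4 mm laterally."""
        spec = PhantomSpec()
        assert (spec.n_z, spec.n_x) == (256, 256)
        assert spec.n_x * spec.pixel_x_um == pytest.approx(4000.0)

    def test_json_roundtrip(self, tmp_path):
        spec = seven_region_spec(n_frames=8, max_pressure_kPa=1.0, n_z=64, n_x=32)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = PhantomSpec.from_file(path)
        assert back.n_z == spec.n_z
        assert np.array_equal(back.region_map, spec.region_map)
        assert np.allclose(back.pressure_schedule, spec.pressure_schedule)
        assert back.class_params == spec.class_params


class TestRenderSeries:
    def test_zero_pressure_gives_identical_frames(self):
        sil = PhantomSpec(n_z=64, n_x=32).silicone_px
        spec = PhantomSpec(
            n_z=64,
            n_x=32,
            class_params={0: (100.0, 0.0)},
            region_map=np.zeros((64 - sil, 32), dtype=int),
            pressure_schedule=np.zeros(3),
        )
        series = coce.simulate(spec)
        assert np.array_equal(series.frames[0], series.frames[1])
        assert np.array_equal(series.frames[0], series.frames[2])

    def test_deterministic_under_seed(self):
        spec_a = seven_region_spec(n_frames=5, max_pressure_kPa=0.5, n_z=64, n_x=32,
                                   snr_db=20.0, seed=9)
        spec_b = seven_region_spec(n_frames=5, max_pressure_kPa=0.5, n_z=64, n_x=32,
                                   snr_db=20.0, seed=9)
        a = coce.simulate(spec_a)
        b = coce.simulate(spec_b)
        assert np.array_equal(a.frames, b.frames)

    def test_uniform_strain_phase_slope(self):
        """Interframe phase gradient is 4*pi*n*strain/lambda0 in geometric depth."""
        from coce.experiments import uniform_strain_series

        series = uniform_strain_series(1e-3, n_frames=2)
        product = series.frames[1] * np.conj(series.frames[0])
        dphi = np.angle(product[1:, :] * np.conj(product[:-1, :]))
        meta = series.meta
        pixel_z_geo_um = meta.pixel_z_um / meta.n_tissue
        slope_per_um = np.median(dphi) / pixel_z_geo_um
        expected = 4 * np.pi * 1.4 * 1e-3 / 1.3  # 0.013534 rad/um
        assert slope_per_um == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.013534, abs=2e-6)

    def test_wrapping_refusal(self):
        sil = PhantomSpec(n_z=64, n_x=16).silicone_px
        spec = PhantomSpec(
            n_z=64,
            n_x=16,
            class_params={0: (10.0, 0.0)},
            region_map=np.zeros((64 - sil, 16), dtype=int),
            pressure_schedule=np.array([0.0, 2.8]),  # 28 % strain in one step
        )
        with pytest.raises(ValueError, match="wrap"):
            coce.simulate(spec)

    def test_scatterer_model_consistent_with_phase_model(self):
        """Full scatterer re-rendering recovers the same strain field coarsely."""
        from coce.strain import interframe_product, vector_strain

        sil = PhantomSpec(n_z=96, n_x=48).silicone_px
        spec = PhantomSpec(
            n_z=96,
            n_x=48,
            class_params={0: (100.0, 0.0)},
            region_map=np.zeros((96 - sil, 48), dtype=int),
            pressure_schedule=np.array([0.0, 0.1]),
            seed=3,
        )
        gt = make_ground_truth(spec)
        series = render_series(spec, gt, signal_model="scatterer")
        fld = vector_strain(
            interframe_product(series.frames[0], series.frames[1]), 96.0, series.meta
        )
        interior = fld.values[20:-20, 10:-10]
        assert np.median(interior) == pytest.approx(1e-3, rel=0.15)
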