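"""Silicone stress sensor, ROI handling, and stress-strain curve assembly."""

import numpy as np
import pytest

import coce
from coce.series import AcquisitionMetadata, BScanSeries
from coce.strain import accumulate_strain, window_px
from coce.stress import (
    GUARD_PX,
    StressStrainCurve,
    build_curves,
    curves_from_csv,
    curves_to_csv,
    lateral_windows,
    silicone_roi,
    stress_from_silicone,
)


def _curves_for(series, window_um=96.0):
    stack = accumulate_strain(series, window_um)
    roi = silicone_roi(series, window_um=window_um)
    _, wx = window_px(window_um, series.meta)
    traces = stress_from_silicone(stack, roi, lateral_windows(series.shape[1], wx))
    return build_curves(traces, stack, window_um), stack, traces


class TestSiliconeRoi:
    def test_metadata_guards(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((2, 128, 8)) + 1j * rng.standard_normal((2, 128, 8))
        meta = AcquisitionMetadata(silicone_px=60)
        series = BScanSeries(frames, meta)
        assert silicone_roi(series) == (2, 57)

    def test_detection_close_to_truth(self, small_seven_region):
        from coce.stress import detect_interface

        spec, series = small_seven_region
        detected = detect_interface(series)
        assert abs(detected - spec.silicone_px) <= 2

    def test_detection_fails_on_uniform_medium(self):
        from coce.experiments import uniform_strain_series
        from coce.stress import detect_interface

        series = uniform_strain_series(1e-3, n_frames=3)
        with pytest.raises(ValueError, match="metadata"):
            detect_interface(series)

    def test_too_thin_layer(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((2, 64, 8)) + 1j * rng.standard_normal((2, 64, 8))
        series = BScanSeries(frames, AcquisitionMetadata(silicone_px=4))
        with pytest.raises(ValueError, match="too thin"):
            silicone_roi(series)


class TestStressFromSilicone:
    def test_hookes_law_recovery(self, small_seven_region):
        """Recovered stress matches the applied schedule to 2 % (noise-free)."""
        spec, series = small_seven_region
        _, stack, traces = _curves_for(series)
        for t in traces[:: len(traces) // 5]:
            true = series.ground_truth["stress_kPa"][:, t.x0 : t.x0 + t.wx].mean(axis=1)
            sel = true > 0.1
            assert np.abs(t.stress_kPa[sel] / true[sel] - 1.0).max() < 0.02

    def test_zero_strain_zero_stress(self):
        from coce.experiments import uniform_strain_series

        series = uniform_strain_series(0.0, n_frames=3)
        _, _, traces = _curves_for(series)
        assert np.allclose(traces[0].stress_kPa, 0.0, atol=1e-9)

    def test_negative_strain_flags_frames(self):
        from coce.strain import StrainStack

        meta = AcquisitionMetadata(silicone_px=30)
        cum = np.zeros((4, 64, 16))
        cum[2, :30, :] = -5e-3  # loss of contact at frame 2
        stack = StrainStack(np.zeros((3, 64, 16)), cum, np.ones((3, 64, 16)), meta)
        traces = stress_from_silicone(stack, (2, 27), [(0, 16)])
        assert traces[0].valid.tolist() == [True, True, False, True]


class TestBuildCurves:
    def test_linear_tissue_gives_linear_curve(self):
        sil = coce.PhantomSpec(n_z=96, n_x=48).silicone_px
        spec = coce.PhantomSpec(
            n_z=96,
            n_x=48,
            class_params={0: (100.0, 0.0)},
            region_map=np.zeros((96 - sil, 48), dtype=int),
            pressure_schedule=np.linspace(0, 3.0, 25),
        )
        series = coce.simulate(spec)
        curves, *_ = _curves_for(series)
        c = [c for c in curves if c.usable][len(curves) // 3]
        slope = np.polyfit(c.strain, c.stress_kPa, 1)[0]
        assert slope == pytest.approx(100.0, rel=0.01)

    def test_window_inside_silicone_sees_sensor_modulus(self, small_seven_region):
        """A curve built over silicone rows has slope E_sil (self-consistency)."""
        spec, series = small_seven_region
        stack = accumulate_strain(series)
        roi = silicone_roi(series, window_um=96.0)
        _, wx = window_px(96.0, series.meta)
        traces = stress_from_silicone(stack, roi, lateral_windows(series.shape[1], wx))
        curves = build_curves(traces, stack, 96.0, tissue_rows=(roi[0], roi[1]))
        c = [c for c in curves if c.usable][0]
        slope = np.polyfit(c.strain, c.stress_kPa, 1)[0]
        assert slope == pytest.approx(series.meta.E_sil_kPa, rel=0.01)

    def test_quadratic_curve_passes_through_known_point(self, homogeneous_curves):
        """E0=50, beta=10: the curve passes through (1 %, 0.55 kPa) within 2 %."""
        c = [c for c in homogeneous_curves if c.usable][10]
        sigma_at = np.interp(0.01, c.strain, c.stress_kPa)
        assert sigma_at == pytest.approx(0.55, rel=0.02)

    def test_exchange_symmetry(self, homogeneous_curves):
        """All windows of a homogeneous phantom produce the same curve."""
        usable = [c for c in homogeneous_curves if c.usable]
        finals = np.array([c.strain[-1] for c in usable])
        assert finals.std() / finals.mean() < 0.01

    def test_too_few_valid_frames_marks_unusable(self):
        from coce.strain import StrainStack
        from coce.stress import StressTrace

        meta = AcquisitionMetadata(silicone_px=30)
        cum = np.linspace(0, 0.01, 6)[:, None, None] * np.ones((6, 96, 16))
        stack = StrainStack(np.diff(cum, axis=0), cum, np.ones((5, 96, 16)), meta)
        trace = StressTrace(
            x0=0,
            wx=16,
            stress_kPa=np.linspace(0, 1.0, 6),
            valid=np.array([True, True, True, False, False, False]),
            roi_rows=(2, 27),
        )
        curves = build_curves([trace], stack, 96.0)
        assert all(not c.usable for c in curves)

    def test_laterally_varying_pressure_tracked_per_column(self):
        """Each lateral window's trace follows its own local schedule."""
        profile = 0.7 + 0.6 * np.arange(128) / 128
        spec = coce.seven_region_spec(
            n_frames=25, max_pressure_kPa=2.0, n_z=128, n_x=128,
            pressure_profile=profile,
        )
        series = coce.simulate(spec)
        _, _, traces = _curves_for(series)
        lo, hi = traces[2], traces[-3]
        true_lo = series.ground_truth["stress_kPa"][-1, lo.x0 : lo.x0 + lo.wx].mean()
        true_hi = series.ground_truth["stress_kPa"][-1, hi.x0 : hi.x0 + hi.wx].mean()
        assert lo.stress_kPa[-1] == pytest.approx(true_lo, rel=0.02)
        assert hi.stress_kPa[-1] == pytest.approx(true_hi, rel=0.02)
        assert hi.stress_kPa[-1] > lo.stress_kPa[-1] * 1.3


class TestCurveCsv:
    def test_roundtrip_exact(self, tmp_path, homogeneous_curves):
        path = tmp_path / "curves.csv"
        subset = homogeneous_curves[:20]
        curves_to_csv(subset, path)
        back = curves_from_csv(path)
        assert len(back) == len(subset)
        for a, b in zip(subset, back):
            assert np.allclose(a.strain, b.strain, atol=1e-12)
            assert np.allclose(a.stress_kPa, b.stress_kPa, atol=1e-12)
            assert (a.z0, a.x0, a.usable) == (b.z0, b.x0, b.usable)
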