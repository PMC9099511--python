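import logging

import numpy as np
import pytest

import coce

# keep the expected cumulative-strain warnings out of the test log
logging.getLogger("coce.strain").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_seven_region():
    """Noise-free seven-stripe phantom series at reduced scale."""
    spec = coce.seven_region_spec(
        n_frames=30, max_pressure_kPa=2.5, n_z=128, n_x=128, seed=2
    )
    return spec, coce.simulate(spec)


@pytest.fixture(scope="session")
def homogeneous_quadratic():
    """Noise-free homogeneous phantom with E0=50 kPa, beta=10."""
    sil = coce.PhantomSpec(n_z=128, n_x=96).silicone_px
    spec = coce.PhantomSpec(
        n_z=128,
        n_x=96,
        class_params={0: (50.0, 10.0)},
        region_map=np.zeros((128 - sil, 96), dtype=int),
        pressure_schedule=np.linspace(0.0, 6.0, 60),
        seed=4,
    )
    return spec, coce.simulate(spec)


@pytest.fixture(scope="session")
def homogeneous_curves(homogeneous_quadratic):
    """Stress-strain curves of the homogeneous quadratic phantom."""
    from coce.strain import window_px
    from coce.stress import (
        build_curves,
        lateral_windows,
        silicone_roi,
        stress_from_silicone,
    )

    spec, series = homogeneous_quadratic
    stack = coce.accumulate_strain(series)
    roi = silicone_roi(series, window_um=96.0)
    _, wx = window_px(96.0, series.meta)
    traces = stress_from_silicone(stack, roi, lateral_windows(series.shape[1], wx))
    return build_curves(traces, stack, 96.0)
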