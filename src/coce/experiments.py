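"""Self-contained validation experiments on synthetic phantoms.

Each function builds the phantom it needs, runs the full processing chain
(strain -> stress -> curves -> maps -> segmentation) and measures the
result against the generative ground truth.  They are used both by the
test suite and by the reproduction script, so problem sizes and study
conditions (sample geometry, frame counts, noise levels, pressure windows)
are fixed here in one place.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .elasticity import (
    PressureWindow,
    SmoothingConfig,
    extrapolate_zero_stress,
    fit_stress_strain,
    map_elastograms,
    modulus_vs_stress,
    nonlinearity_parameter,
    tangent_modulus,
)
from .phantom import (
    SEVEN_CLASS_PARAMS,
    PhantomSpec,
    make_ground_truth,
    render_series,
    seven_region_spec,
    simulate,
    solve_layer_strain,
    two_class_overlap_spec,
)
from .segmentation import calibrate_ranges, segment
from .strain import accumulate_strain, interframe_product, vector_strain, window_px
from .stress import build_curves, lateral_windows, silicone_roi, stress_from_silicone

__all__ = [
    "constitutive_roundtrip",
    "uniform_strain_series",
    "strain_oracle_check",
    "lsq_phase_slope_oracle",
    "sensor_linearity",
    "consistency_check",
    "process_to_maps",
    "recovery_experiment",
    "pressure_invariance",
    "segmentation_experiment",
    "two_class_experiment",
]


# ---------------------------------------------------------------------------
# 1. constitutive law round trip
# ---------------------------------------------------------------------------

def constitutive_roundtrip(n_per_axis: int = 25) -> dict:
    """Invert then forward-evaluate the quadratic law over a parameter grid.

    Returns the maximum relative error of sigma -> eps -> sigma over
    E0 in [20, 1000] kPa, beta in [0, 50], sigma in [0, 10] kPa.
    """
    E0 = np.linspace(20.0, 1000.0, n_per_axis)
    beta = np.linspace(0.0, 50.0, n_per_axis)
    sigma = np.linspace(0.0, 10.0, n_per_axis)
    ee, bb, ss = np.meshgrid(E0, beta, sigma, indexing="ij")
    eps = solve_layer_strain(ss, ee, bb)
    sigma_back = ee * (eps + bb * eps**2)
    denom = np.where(ss > 0, ss, 1.0)
    rel = np.abs(sigma_back - ss) / denom
    return {"max_rel_err": float(rel.max()), "n": int(ss.size)}


# ---------------------------------------------------------------------------
# 2. strain estimator vs truth and vs brute-force oracle
# ---------------------------------------------------------------------------

def uniform_strain_series(strain_per_frame: float, n_frames: int = 3,
                          n_z: int = 96, n_x: int = 64, seed: int = 0,
                          snr_db: float | None = None):
    """Phantom with spatially uniform strain (tissue matched to the silicone)."""
    spec = PhantomSpec(
        n_z=n_z,
        n_x=n_x,
        class_params={0: (100.0, 0.0)},
        pressure_schedule=np.arange(n_frames) * strain_per_frame * 100.0,
        seed=seed,
        snr_db=snr_db,
    )
    return simulate(spec)


def lsq_phase_slope_oracle(product: np.ndarray, wz: int, wx: int,
                           centers: list[tuple[int, int]],
                           lambda0_um: float, pixel_z_um: float) -> np.ndarray:
    """Brute-force strain oracle: windowed least-squares fit of unwrapped phase.

    For each window centre, the interframe phase of every column is
    unwrapped along depth and regressed on the row index; the per-column
    slopes are averaged.  Entirely independent of the vector estimator.
    """
    out = []
    phase = np.unwrap(np.angle(product), axis=0)
    for zc, xc in centers:
        z0 = zc - wz // 2
        x0 = xc - wx // 2
        block = phase[z0 : z0 + wz, x0 : x0 + wx]
        rows = np.arange(block.shape[0])
        slopes = [np.polyfit(rows, block[:, j], 1)[0] for j in range(block.shape[1])]
        out.append(np.mean(slopes) * lambda0_um / (4.0 * np.pi * pixel_z_um))
    return np.asarray(out)


def strain_oracle_check(strains=(1e-4, 5e-4, 1e-3, 2e-3), window_um: float = 96.0) -> dict:
    """Noise-free uniform-strain phantoms: estimator vs truth and vs LSQ oracle."""
    max_err_truth = 0.0
    max_err_oracle = 0.0
    n = 0
    for s in strains:
        series = uniform_strain_series(s)
        meta = series.meta
        product = interframe_product(series.frames[0], series.frames[1])
        fld = vector_strain(product, window_um, meta)
        wz, wx = window_px(window_um, meta)
        margin_z, margin_x = wz + 8, wx + 2
        interior = fld.values[margin_z:-margin_z, margin_x:-margin_x]
        max_err_truth = max(max_err_truth, float(np.abs(interior - s).max()))
        centers = [
            (zc, xc)
            for zc in range(margin_z, series.shape[0] - margin_z, 7)
            for xc in range(margin_x, series.shape[1] - margin_x, 7)
        ]
        oracle = lsq_phase_slope_oracle(product, wz, wx, centers,
                                        meta.lambda0_um, meta.pixel_z_um)
        est = np.asarray([fld.values[zc, xc] for zc, xc in centers])
        max_err_oracle = max(max_err_oracle, float(np.abs(est - oracle).max()))
        n += interior.size
    return {
        "max_abs_err_vs_truth": max_err_truth,
        "max_abs_err_vs_oracle": max_err_oracle,
        "n": n,
    }


# ---------------------------------------------------------------------------
# 3. silicone stress sensor linearity
# ---------------------------------------------------------------------------

def sensor_linearity(snr_db: float | None = None, seed: int = 0,
                     n: int = 128, n_frames: int = 40,
                     window_um: float = 96.0) -> dict:
    """Regress recovered stress on the applied schedule over all windows."""
    spec = seven_region_spec(n_frames=n_frames, max_pressure_kPa=3.0,
                             snr_db=snr_db, seed=seed, n_z=n, n_x=n)
    series = simulate(spec)
    stack = accumulate_strain(series, window_um)
    roi = silicone_roi(series, window_um=window_um)
    _, wx = window_px(window_um, series.meta)
    traces = stress_from_silicone(stack, roi, lateral_windows(n, wx))
    recovered, applied = [], []
    for t in traces:
        true = series.ground_truth["stress_kPa"][:, t.x0 : t.x0 + t.wx].mean(axis=1)
        recovered.append(t.stress_kPa[t.valid])
        applied.append(true[t.valid])
    x = np.concatenate(applied)
    y = np.concatenate(recovered)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    return {"slope": float(slope), "r2": float(r2), "n": int(x.size)}


# ---------------------------------------------------------------------------
# 4. tangent-modulus / nonlinearity consistency with the analytic transforms
# ---------------------------------------------------------------------------

def consistency_check(E0: float = 50.0, beta: float = 10.0,
                      sigma0_grid=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
                      n: int = 128, n_frames: int = 60,
                      window_um: float = 96.0) -> dict:
    """Noise-free homogeneous quadratic phantom vs the analytic E and beta laws.

    Checks E(sigma0) against E0*(1 + 2*beta*eps(sigma0)) with a vanishing
    pressure window, and beta(sigma0) against beta/(1 + 2*beta*eps(sigma0))
    with the standard +-0.5 kPa window.
    """
    sil = PhantomSpec(n_z=n, n_x=n).silicone_px
    spec = PhantomSpec(
        n_z=n,
        n_x=n,
        class_params={0: (E0, beta)},
        region_map=np.zeros((n - sil, n), dtype=int),
        pressure_schedule=np.linspace(0.0, 6.0, n_frames),
    )
    series = simulate(spec)
    stack = accumulate_strain(series, window_um)
    roi = silicone_roi(series, window_um=window_um)
    _, wx = window_px(window_um, series.meta)
    traces = stress_from_silicone(stack, roi, lateral_windows(n, wx))
    curves = build_curves(traces, stack, window_um)
    mid = [c for c in curves if c.usable][len(curves) // 2]
    law = fit_stress_strain(mid)
    E_dev = beta_dev = 0.0
    for s0 in sigma0_grid:
        eps0 = solve_layer_strain(s0, E0, beta)
        E_true = E0 * (1.0 + 2.0 * beta * eps0)
        E_est = tangent_modulus(law, PressureWindow(s0, 1e-6))
        E_dev = max(E_dev, abs(E_est / E_true - 1.0))
        beta_true = beta / (1.0 + 2.0 * beta * eps0)
        beta_est = nonlinearity_parameter(modulus_vs_stress(law, 200),
                                          PressureWindow(s0, 0.5))
        beta_dev = max(beta_dev, abs(beta_est / beta_true - 1.0))
    return {
        "max_E_rel_dev": float(E_dev),
        "max_beta_rel_dev": float(beta_dev),
        "n": len(sigma0_grid),
    }


# ---------------------------------------------------------------------------
# full chain helper + parameter recovery
# ---------------------------------------------------------------------------

def process_to_maps(series, window: PressureWindow, window_um: float = 96.0,
                    smoothing: SmoothingConfig | None = None):
    """series -> strain -> stress -> curves -> (E, beta) maps."""
    stack = accumulate_strain(series, window_um)
    roi = silicone_roi(series, window_um=window_um)
    _, wx = window_px(window_um, series.meta)
    traces = stress_from_silicone(stack, roi, lateral_windows(series.shape[1], wx))
    curves = build_curves(traces, stack, window_um)
    pair = map_elastograms(
        curves, window, series.shape, smoothing,
        pixel_z_um=series.meta.pixel_z_um, pixel_x_um=series.meta.pixel_x_um,
    )
    return pair, curves


def _region_selectors(spec, series_shape):
    """Full-grid boolean mask per region label of a phantom."""
    sil = series_shape[0] - spec.region_map.shape[0]
    out = {}
    for label in np.unique(spec.region_map):
        sel = np.zeros(series_shape, dtype=bool)
        sel[sil:, :] = spec.region_map == label
        out[int(label)] = sel
    return out


def recovery_experiment(seed: int = 11, snr_db: float | None = 20.0,
                        n: int = 256, n_frames: int = 50,
                        sigma0: float = 0.5, tol: float = 0.5) -> dict:
    """Joint (E0, beta) recovery on the seeded seven-region phantom.

    Maps are computed at the standardized pressure window and extrapolated
    back to zero stress through the quadratic-law transform before
    comparison with the generative parameters.  Reports the worst
    per-region median relative error for E0 and for beta.
    """
    spec = seven_region_spec(n_frames=n_frames, max_pressure_kPa=3.0,
                             snr_db=snr_db, seed=seed, n_z=n, n_x=n)
    series = simulate(spec)
    pair, _ = process_to_maps(series, PressureWindow(sigma0, tol))
    names = list(SEVEN_CLASS_PARAMS)
    selectors = _region_selectors(spec, series.shape)
    per_region = {}
    for label, sel in selectors.items():
        sel = sel & pair.mask & np.isfinite(pair.beta_map)
        E0_t, beta_t = spec.class_params[label]
        rec = np.array(
            [extrapolate_zero_stress(e, b, sigma0)
             for e, b in zip(pair.E_map[sel], pair.beta_map[sel])]
        )
        per_region[names[label]] = {
            "median_rel_err_E0": float(np.nanmedian(np.abs(rec[:, 0] / E0_t - 1.0))),
            "median_rel_err_beta": float(np.nanmedian(np.abs(rec[:, 1] / beta_t - 1.0))),
            "n_px": int(sel.sum()),
        }
    return {
        "per_region": per_region,
        "worst_E0": max(r["median_rel_err_E0"] for r in per_region.values()),
        "worst_beta": max(r["median_rel_err_beta"] for r in per_region.values()),
        "n": sum(r["n_px"] for r in per_region.values()),
    }


# ---------------------------------------------------------------------------
# pressure-standardization invariance
# ---------------------------------------------------------------------------

def pressure_invariance(seed: int = 0, n: int = 256, n_frames: int = 50,
                        sigma0: float = 0.5, tol: float = 0.5) -> dict:
    """Same tissue, two laterally non-uniform pressure schedules.

    The standardized-pressure E maps must agree wherever both are valid:
    that is the point of evaluating stiffness at a fixed local stress.
    """
    x = np.arange(n) / n
    profiles = (0.8 + 0.4 * x, 1.2 - 0.4 * x)
    pairs = []
    for k, prof in enumerate(profiles):
        spec = seven_region_spec(n_frames=n_frames, max_pressure_kPa=3.0,
                                 seed=seed, n_z=n, n_x=n, pressure_profile=prof)
        series = simulate(spec)
        pair, _ = process_to_maps(series, PressureWindow(sigma0, tol))
        pairs.append(pair)
    both = pairs[0].mask & pairs[1].mask
    rel = np.abs(pairs[0].E_map[both] - pairs[1].E_map[both]) / pairs[0].E_map[both]
    return {
        "median_rel_disagreement": float(np.median(rel)),
        "p95_rel_disagreement": float(np.percentile(rel, 95)),
        "n": int(both.sum()),
    }


# ---------------------------------------------------------------------------
# segmentation experiments
# ---------------------------------------------------------------------------

def _calibration_samples(pair, spec, series_shape, names, wz, wx, thin=5):
    """Labelled (E, beta) samples from the interior of each known region."""
    footprint = np.ones((2 * wz + 1, 2 * wx + 1), dtype=bool)
    samples = []
    for label, sel in _region_selectors(spec, series_shape).items():
        interior = ndimage.binary_erosion(sel, structure=footprint)
        interior &= pair.mask & np.isfinite(pair.beta_map)
        zz, xx = np.nonzero(interior)
        for z, x in zip(zz[::thin], xx[::thin]):
            samples.append((float(pair.E_map[z, x]), float(pair.beta_map[z, x]),
                            names[label]))
    return samples


def _interior_accuracy(seg, pair, spec, series_shape, names, wz, wx):
    """Pixel accuracy over valid pixels outside a one-window boundary band."""
    footprint = np.ones((2 * wz + 1, 2 * wx + 1), dtype=bool)
    name_to_idx = {n: i for i, n in enumerate(seg.class_names)}
    correct = total = 0
    for label, sel in _region_selectors(spec, series_shape).items():
        interior = ndimage.binary_erosion(sel, structure=footprint)
        interior &= pair.mask & np.isfinite(pair.beta_map)
        want = name_to_idx.get(names[label], -99)
        got = seg.labels[interior]
        correct += int(np.sum(got == want))
        total += int(got.size)
    return correct / max(total, 1), total


def segmentation_experiment(seed: int = 3, snr_db: float | None = None,
                            n: int = 256, n_frames: int = 50,
                            sigma0: float = 0.5, tol: float = 0.5) -> dict:
    """Calibrate class boxes on a seven-region phantom and segment it."""
    spec = seven_region_spec(n_frames=n_frames, max_pressure_kPa=3.0,
                             snr_db=snr_db, seed=seed, n_z=n, n_x=n)
    series = simulate(spec)
    pair, _ = process_to_maps(series, PressureWindow(sigma0, tol))
    names = list(SEVEN_CLASS_PARAMS)
    wz, wx = window_px(96.0, series.meta)
    samples = _calibration_samples(pair, spec, series.shape, names, wz, wx)
    ranges = calibrate_ranges(samples)
    seg = segment(pair, ranges)
    acc, n_eval = _interior_accuracy(seg, pair, spec, series.shape, names, wz, wx)
    return {"accuracy": acc, "n": n_eval, "ranges": ranges, "segmentation": seg}


def two_class_experiment(seed: int = 5, snr_db: float | None = 20.0,
                         n: int = 256, n_frames: int = 50,
                         sigma0: float = 0.5, tol: float = 0.5) -> dict:
    """Overlapping-stiffness two-class phantom: (E, beta) boxes vs E alone.

    The two classes are built to overlap in stiffness but differ strongly
    in nonlinearity.  Reports the box-segmentation accuracy and the best
    accuracy achievable by sweeping every single-threshold classifier on
    the E map alone (both polarities).
    """
    spec, stripe_class = two_class_overlap_spec(n_frames=n_frames, seed=seed,
                                                snr_db=snr_db, n_z=n, n_x=n)
    series = simulate(spec)
    pair, _ = process_to_maps(series, PressureWindow(sigma0, tol))
    class_names = {0: "nearly linear (fibrosis-like)", 1: "strongly nonlinear (scirrhous-like)"}
    names = {label: class_names[stripe_class[label]] for label in spec.class_params}
    wz, wx = window_px(96.0, series.meta)
    samples = _calibration_samples(pair, spec, series.shape, names, wz, wx)
    ranges = calibrate_ranges(samples)
    seg = segment(pair, ranges)
    acc, n_eval = _interior_accuracy(seg, pair, spec, series.shape, names, wz, wx)

    # single-parameter sweep on the same evaluation pixels
    footprint = np.ones((2 * wz + 1, 2 * wx + 1), dtype=bool)
    E_vals, truth = [], []
    for label, sel in _region_selectors(spec, series.shape).items():
        interior = ndimage.binary_erosion(sel, structure=footprint)
        interior &= pair.mask & np.isfinite(pair.beta_map)
        E_vals.append(pair.E_map[interior])
        truth.append(np.full(int(interior.sum()), stripe_class[label]))
    E_vals = np.concatenate(E_vals)
    truth = np.concatenate(truth)
    thresholds = np.quantile(E_vals, np.linspace(0.0, 1.0, 201))
    best = 0.0
    for thr in thresholds:
        pred = (E_vals > thr).astype(int)
        a = max(np.mean(pred == truth), np.mean((1 - pred) == truth))
        best = max(best, float(a))
    return {
        "box_accuracy": acc,
        "best_E_threshold_accuracy": best,
        "n": n_eval,
    }
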