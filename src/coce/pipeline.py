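"""End-to-end pipeline: simulate -> strain -> curves -> maps -> segmentation.

Every run writes a JSON manifest recording the package version, seed,
parameters, per-stage wall times, and SHA-256 checksums of all artifacts.
All randomness flows from the single top-level seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .elasticity import ElastogramPair, PressureWindow, SmoothingConfig, map_elastograms
from .phantom import PhantomSpec, seven_region_spec, simulate
from .series import BScanSeries
from .strain import DEFAULT_WINDOW_UM, accumulate_strain, window_px
from .stress import (
    build_curves,
    curves_to_csv,
    lateral_windows,
    silicone_roi,
    stress_from_silicone,
)
from .segmentation import ClassRangeSet, calibrate_ranges, segment

__all__ = ["PipelineConfig", "run_pipeline", "save_strain_stack", "load_strain_stack"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full processing run.

    Exactly one of ``input_h5`` (a measured/simulated series on disk),
    ``phantom_spec`` (path to a JSON/YAML phantom document) or
    ``demo`` (bundled seven-region phantom) must select the input.
    """

    out_dir: str = "oce_out"
    input_h5: str | None = None
    phantom_spec: str | None = None
    demo: bool = False
    snr_db: float | None = 20.0
    window_um: float = DEFAULT_WINDOW_UM
    pressure_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.5, 0.5), (4.0, 0.5)]
    )
    fit_backend: str = "spline"
    ranges_json: str | None = None
    calibrate_from_ground_truth: bool = False
    run_segmentation: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if "pressure_windows" in doc:
            doc["pressure_windows"] = [tuple(w) for w in doc["pressure_windows"]]
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_strain_stack(stack, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.require_group("strain")
        g.create_dataset("interframe", data=stack.interframe.astype(np.float32), track_times=False)
        g.create_dataset("cumulative", data=stack.cumulative.astype(np.float32), track_times=False)
        g.create_dataset("quality", data=stack.quality.astype(np.float32), track_times=False)


def load_strain_stack(path: Path):
    import h5py

    with h5py.File(path, "r") as f:
        g = f["strain"]
        return g["interframe"][...], g["cumulative"][...], g["quality"][...]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage failure is re-raised with a stage-tagged message; artifacts
    produced by earlier stages are retained in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "window_um": config.window_um,
            "pressure_windows": [list(w) for w in config.pressure_windows],
            "fit_backend": config.fit_backend,
            "snr_db": config.snr_db,
        },
        "stages": {},
        "artifacts": {},
    }
    stage = "configure"
    try:
        # ------------------------------------------------------ input stage
        stage = "simulate"
        t0 = time.perf_counter()
        rng_root = np.random.SeedSequence(config.seed)
        truth_labels = None
        if config.demo:
            spec = seven_region_spec(
                snr_db=config.snr_db,
                seed=int(rng_root.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)),
            )
            series = simulate(spec)
            truth_labels = spec.region_map
            series_path = out / "phantom.h5"
            series.to_hdf5(series_path)
            manifest["artifacts"]["series"] = str(series_path)
        elif config.phantom_spec:
            spec = PhantomSpec.from_file(config.phantom_spec)
            series = simulate(spec)
            truth_labels = spec.region_map
            series_path = out / "phantom.h5"
            series.to_hdf5(series_path)
            manifest["artifacts"]["series"] = str(series_path)
        elif config.input_h5:
            series = BScanSeries.from_hdf5(config.input_h5)
            manifest["artifacts"]["series"] = str(config.input_h5)
        else:
            raise ValueError("config selects no input (input_h5 / phantom_spec / demo)")
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------------ strain stage
        stage = "strain"
        t0 = time.perf_counter()
        stack = accumulate_strain(series, config.window_um)
        strain_path = out / "strains.h5"
        save_strain_stack(stack, strain_path)
        manifest["artifacts"]["strain"] = str(strain_path)
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------------ curves stage
        stage = "curves"
        t0 = time.perf_counter()
        roi = silicone_roi(series, window_um=config.window_um)
        _, wx = window_px(config.window_um, series.meta)
        windows = lateral_windows(series.shape[1], wx)
        traces = stress_from_silicone(stack, roi, windows)
        curves = build_curves(traces, stack, config.window_um)
        curves_path = out / "curves.csv"
        curves_to_csv(curves, curves_path)
        manifest["artifacts"]["curves"] = str(curves_path)
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------------ maps stage
        stage = "maps"
        t0 = time.perf_counter()
        smoothing = SmoothingConfig(backend=config.fit_backend)
        pairs: list[ElastogramPair] = []
        for sigma0, tol in config.pressure_windows:
            pw = PressureWindow(sigma0, tol)
            pair = map_elastograms(
                curves,
                pw,
                series.shape,
                smoothing,
                pixel_z_um=series.meta.pixel_z_um,
                pixel_x_um=series.meta.pixel_x_um,
            )
            tag = f"maps_sigma{sigma0:g}"
            map_path = out / f"{tag}.h5"
            pair.to_hdf5(map_path)
            pair.render_png(out / f"{tag}.png")
            manifest["artifacts"][tag] = str(map_path)
            pairs.append(pair)
        manifest["stages"][stage] = time.perf_counter() - t0

        # ------------------------------------------------ segmentation stage
        stage = "segment"
        if config.run_segmentation:
            t0 = time.perf_counter()
            if config.ranges_json:
                ranges = ClassRangeSet.from_json(config.ranges_json)
            elif config.calibrate_from_ground_truth and truth_labels is not None:
                ranges = _calibrate_from_truth(pairs[0], truth_labels, series.meta, spec)
                ranges_path = out / "ranges.json"
                ranges.to_json(ranges_path)
                manifest["artifacts"]["ranges"] = str(ranges_path)
            else:
                raise ValueError(
                    "segmentation requested but no ranges_json given and "
                    "ground-truth calibration unavailable"
                )
            seg = segment(pairs[0], ranges)
            seg_path = out / "segmentation.tiff"
            seg.to_tiff(seg_path)
            seg.render_png(out / "segmentation.png")
            seg.fractions_to_csv(out / "segmentation_fractions.csv")
            manifest["artifacts"]["segmentation"] = str(seg_path)
            manifest["stages"][stage] = time.perf_counter() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest["checksums"] = {
        key: _sha256(Path(p)) for key, p in manifest["artifacts"].items() if Path(p).exists()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _calibrate_from_truth(pair, region_map, meta, spec) -> ClassRangeSet:
    """Class boxes from the elastogram pixels of each known phantom region."""
    labels_by_idx = {i: name for i, name in enumerate(_class_names_of(spec))}
    sil = meta.silicone_px
    samples = []
    E, B = pair.E_map, pair.beta_map
    for label, name in labels_by_idx.items():
        sel = np.zeros(E.shape, dtype=bool)
        sel[sil:, :] = region_map == label
        sel &= pair.mask & np.isfinite(B)
        zz, xx = np.nonzero(sel)
        for z, x in zip(zz[::7], xx[::7]):  # thin to keep calibration light
            samples.append((float(E[z, x]), float(B[z, x]), name))
    return calibrate_ranges(samples)


def _class_names_of(spec) -> list[str]:
    from .phantom import SEVEN_CLASS_PARAMS

    names = list(SEVEN_CLASS_PARAMS)
    if len(spec.class_params) == len(names):
        return names
    return [f"class {label}" for label in sorted(spec.class_params)]
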