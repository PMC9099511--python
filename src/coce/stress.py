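"""Local stress from the reference silicone and per-window stress-strain curves.

The precalibrated silicone layer between the probe and the tissue is highly
linear, so its local cumulative strain times its Young's modulus gives the
local axial stress.  Because the probe is much wider than the imaging
depth, the stress is depth-independent within each lateral column and a
single stress trace per lateral window is shared by every depth below it.
Pairing that trace with the windowed cumulative tissue strain across frames
yields one stress-strain curve per processing window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BScanSeries
from .strain import DEFAULT_WINDOW_UM, StrainStack, window_px

__all__ = [
    "StressTrace",
    "StressStrainCurve",
    "silicone_roi",
    "detect_interface",
    "stress_from_silicone",
    "build_curves",
    "lateral_windows",
    "curves_to_csv",
    "curves_from_csv",
]

log = logging.getLogger(__name__)

#: rows skipped at each silicone boundary (probe face and tissue interface)
GUARD_PX = 2

#: tolerated negative mean silicone strain before a frame is declared
#: out of contact
NEG_STRAIN_TOL = 1e-4

MIN_VALID_FRAMES = 5


@dataclass
class StressTrace:
    """Per-frame local stress for one lateral window."""

    x0: int
    wx: int
    stress_kPa: np.ndarray  # (F,)
    valid: np.ndarray  # (F,) bool
    roi_rows: tuple[int, int]  # inclusive silicone row range used

    @property
    def x_center(self) -> float:
        return self.x0 + (self.wx - 1) / 2.0


@dataclass
class StressStrainCurve:
    """Paired (cumulative tissue strain, silicone-derived stress) vs frame."""

    z0: int
    x0: int
    wz: int
    wx: int
    z_center_um: float
    x_center_um: float
    strain: np.ndarray
    stress_kPa: np.ndarray
    usable: bool = True
    window_id: int = -1
    note: str = ""

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_kPa = np.asarray(self.stress_kPa, dtype=float)
        if self.strain.shape != self.stress_kPa.shape:
            raise ValueError("strain and stress sequences must have equal length")


def silicone_roi(
    series: BScanSeries,
    guard_px: int = GUARD_PX,
    detect: bool = False,
    window_um: float | tuple[float, float] | None = None,
) -> tuple[int, int]:
    """Silicone row range (inclusive) after guard bands at both boundaries.

    Metadata-first: uses ``meta.silicone_px`` unless ``detect=True``, in which
    case the silicone-tissue interface is located from the axial strain
    discontinuity of the series itself.

    When ``window_um`` is given, the tissue-side guard is widened to half
    the strain-estimation window (plus the geometric guard): the windowed
    estimator mixes tissue strain into the estimates within half a window
    of the interface, which would bias the stress sensor wherever the
    tissue is much softer or stiffer than the silicone.
    """
    if detect:
        sil_px = detect_interface(series)
    else:
        sil_px = series.meta.silicone_px
    guard_tissue = guard_px
    if window_um is not None:
        wz, _ = window_px(window_um, series.meta)
        guard_tissue = max(guard_px, wz // 2 + 2)
    lo = guard_px
    hi = sil_px - guard_tissue - 1
    if hi <= lo:
        raise ValueError(
            f"silicone layer of {sil_px} rows too thin for its guard bands"
        )
    return lo, hi


def detect_interface(series: BScanSeries) -> int:
    """Locate the silicone-tissue interface row from the strain discontinuity.

    Uses the interframe strain of the last frame pair (largest pressure
    increment available), column-medianed into a depth profile; the
    interface is the largest jump of that profile.  Fails with guidance to
    use metadata when no clear discontinuity exists (e.g. a mechanically
    uniform sample).
    """
    from .strain import interframe_product, vector_strain

    frames = series.frames
    product = interframe_product(frames[-2], frames[-1])
    fld = vector_strain(product, DEFAULT_WINDOW_UM, series.meta)
    profile = np.median(fld.values, axis=1)
    jumps = np.abs(np.diff(profile))
    wz, _ = window_px(DEFAULT_WINDOW_UM, series.meta)
    inner = jumps[wz : len(jumps) - wz]
    if inner.size == 0:
        raise ValueError("image too shallow for interface detection; use metadata")
    k = int(np.argmax(inner)) + wz
    background = np.median(jumps)
    if jumps[k] < 10.0 * max(background, 1e-9) or jumps[k] < 1e-5:
        raise ValueError(
            "no strain discontinuity found: cannot auto-detect the "
            "silicone-tissue interface; provide silicone_px in the metadata"
        )
    # the vector window smears the step over ~wz rows; the interface sits at
    # the centre of the transition
    return k + 1


def lateral_windows(n_x: int, wx: int, stride: int | None = None) -> list[tuple[int, int]]:
    """Tiling of the lateral axis into (x0, wx) windows, stride = wx//2 default."""
    stride = stride or max(wx // 2, 1)
    starts = list(range(0, n_x - wx + 1, stride))
    if starts and starts[-1] != n_x - wx:
        starts.append(n_x - wx)
    return [(x0, wx) for x0 in starts]


def stress_from_silicone(
    stack: StrainStack,
    roi: tuple[int, int],
    windows: list[tuple[int, int]] | None = None,
    E_sil_kPa: float | None = None,
    neg_tol: float = NEG_STRAIN_TOL,
) -> list[StressTrace]:
    """Hooke's-law stress traces from windowed silicone cumulative strain.

    The silicone strain is depth-collapsed by the arithmetic mean over the
    ROI rows (the layer is homogeneous and linear).  Frames whose mean
    silicone strain is negative beyond ``neg_tol`` are flagged invalid
    (loss of probe contact).
    """
    E_sil = E_sil_kPa if E_sil_kPa is not None else stack.meta.E_sil_kPa
    if E_sil <= 0:
        raise ValueError("silicone Young's modulus must be positive")
    lo, hi = roi
    cum = stack.cumulative  # (F, Z, X)
    if windows is None:
        _, wx = window_px(DEFAULT_WINDOW_UM, stack.meta)
        windows = lateral_windows(cum.shape[2], wx)
    traces = []
    sil = cum[:, lo : hi + 1, :]  # (F, rows, X)
    for x0, wx in windows:
        eps_sil = sil[:, :, x0 : x0 + wx].mean(axis=(1, 2))
        valid = eps_sil > -neg_tol
        traces.append(
            StressTrace(
                x0=x0,
                wx=wx,
                stress_kPa=E_sil * eps_sil,
                valid=valid,
                roi_rows=(lo, hi),
            )
        )
    return traces


def build_curves(
    traces: list[StressTrace],
    stack: StrainStack,
    window_um: float | tuple[float, float] = DEFAULT_WINDOW_UM,
    z_stride: int | None = None,
    tissue_rows: tuple[int, int] | None = None,
    min_valid_frames: int = MIN_VALID_FRAMES,
) -> list[StressStrainCurve]:
    """One stress-strain curve per tissue processing window.

    Windows tile the tissue zone with stride = half window in both axes;
    the lateral positions are those of ``traces``.  Strain is the window
    mean of the cumulative tissue strain; stress comes from the same
    lateral window's trace.  Invalid frames are dropped pairwise and each
    curve is re-based so its first valid frame defines (0, 0); curves with
    fewer than ``min_valid_frames`` valid frames are marked unusable.
    """
    meta = stack.meta
    wz, wx = window_px(window_um, meta)
    z_stride = z_stride or max(wz // 2, 1)
    cum = stack.cumulative
    n_z = cum.shape[1]
    # the strain estimate within half a window of the interface mixes
    # silicone strain; start tissue windows below that transition band
    z_lo = tissue_rows[0] if tissue_rows else meta.silicone_px + max(GUARD_PX, wz // 2 + 2)
    z_hi = tissue_rows[1] if tissue_rows else n_z - 1
    z_starts = list(range(z_lo, z_hi - wz + 2, z_stride))
    curves: list[StressStrainCurve] = []
    wid = 0
    for trace in traces:
        x0 = trace.x0
        valid = trace.valid
        for z0 in z_starts:
            strain_seq = cum[:, z0 : z0 + wz, x0 : x0 + trace.wx].mean(axis=(1, 2))
            stress_seq = trace.stress_kPa
            s_ok = strain_seq[valid]
            p_ok = stress_seq[valid]
            usable = s_ok.size >= min_valid_frames
            note = "" if usable else f"only {s_ok.size} valid frames"
            if s_ok.size:
                s_ok = s_ok - s_ok[0]
                p_ok = p_ok - p_ok[0]
            z_center = z0 + (wz - 1) / 2.0
            x_center = x0 + (trace.wx - 1) / 2.0
            curves.append(
                StressStrainCurve(
                    z0=z0,
                    x0=x0,
                    wz=wz,
                    wx=trace.wx,
                    z_center_um=z_center * meta.pixel_z_um / meta.n_tissue,
                    x_center_um=x_center * meta.pixel_x_um,
                    strain=s_ok,
                    stress_kPa=p_ok,
                    usable=usable,
                    window_id=wid,
                    note=note,
                )
            )
            wid += 1
    return curves


def curves_to_csv(curves: list[StressStrainCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for f, (eps, sig) in enumerate(zip(c.strain, c.stress_kPa)):
            rows.append(
                {
                    "window_id": c.window_id,
                    "z0_px": c.z0,
                    "x0_px": c.x0,
                    "wz_px": c.wz,
                    "wx_px": c.wx,
                    "z_um": c.z_center_um,
                    "x_um": c.x_center_um,
                    "frame": f,
                    "strain": eps,
                    "stress_kPa": sig,
                    "usable": c.usable,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def curves_from_csv(path: str | Path) -> list[StressStrainCurve]:
    df = pd.read_csv(path)
    curves = []
    for wid, grp in df.groupby("window_id", sort=True):
        grp = grp.sort_values("frame")
        first = grp.iloc[0]
        curves.append(
            StressStrainCurve(
                z0=int(first["z0_px"]),
                x0=int(first["x0_px"]),
                wz=int(first["wz_px"]),
                wx=int(first["wx_px"]),
                z_center_um=float(first["z_um"]),
                x_center_um=float(first["x_um"]),
                strain=grp["strain"].to_numpy(),
                stress_kPa=grp["stress_kPa"].to_numpy(),
                usable=bool(first["usable"]),
                window_id=int(wid),
            )
        )
    return curves
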