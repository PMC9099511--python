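"""Two-parameter (E, beta) morphological segmentation of elastogram pairs.

Each tissue class occupies an axis-aligned box on the (E, beta) plane,
calibrated from labelled samples.  A pixel is assigned the highest-priority
box containing its (E, beta) pair; pixels outside all boxes stay
"unclassified" and masked pixels stay "masked" — neither is merged into a
tissue class.  The box representation is deliberately simple: stiffness
ranges for single classes are intervals per axis, overlap between classes
in one parameter is resolved by the other parameter or, residually, by the
deterministic priority order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .elasticity import ElastogramPair

__all__ = [
    "ClassRange",
    "ClassRangeSet",
    "SegmentationMap",
    "calibrate_ranges",
    "classify_point",
    "segment",
    "DEFAULT_CLASS_NAMES",
    "DEFAULT_PALETTE",
]

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
MASKED = "masked"

#: the seven breast-tissue morphotypes used as the default class vocabulary
DEFAULT_CLASS_NAMES = (
    "adipose",
    "fibrous stroma",
    "IDC scirrhous",
    "IDC solid-scirrhous",
    "IDC solid",
    "ILC solid",
    "hyalinosis",
)

#: display colors (hex): dark-blue adipose, light-blue fibrosis, green
#: scattered cancer cells, orange cell clusters, red IDC, magenta ILC,
#: black hyalinosis
DEFAULT_PALETTE = {
    "adipose": "#00008B",
    "fibrous stroma": "#87CEEB",
    "IDC scirrhous": "#228B22",
    "IDC solid-scirrhous": "#FFA500",
    "IDC solid": "#FF0000",
    "ILC solid": "#FF00FF",
    "hyalinosis": "#000000",
}


@dataclass
class ClassRange:
    """Characteristic (E, beta) box of one tissue class."""

    name: str
    e_min: float
    e_max: float
    beta_min: float
    beta_max: float
    color: str = "#808080"
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.e_min < self.e_max:
            raise ValueError(f"{self.name}: need e_min < e_max")
        if not self.beta_min < self.beta_max:
            raise ValueError(f"{self.name}: need beta_min < beta_max")

    def contains(self, E, beta):
        return (
            (E >= self.e_min)
            & (E <= self.e_max)
            & (beta >= self.beta_min)
            & (beta <= self.beta_max)
        )

    def overlaps(self, other: "ClassRange") -> bool:
        return (
            self.e_min < other.e_max
            and other.e_min < self.e_max
            and self.beta_min < other.beta_max
            and other.beta_min < self.beta_max
        )


@dataclass
class ClassRangeSet:
    """Ordered collection of class boxes with unique priorities."""

    ranges: list[ClassRange] = field(default_factory=list)

    def __post_init__(self) -> None:
        prios = [r.priority for r in self.ranges]
        if len(set(prios)) != len(prios):
            raise ValueError("class priorities must be unique")
        names = [r.name for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self):
        return len(self.ranges)

    def by_priority(self) -> list[ClassRange]:
        return sorted(self.ranges, key=lambda r: -r.priority)

    def overlap_report(self) -> list[tuple[str, str]]:
        """Pairs of classes whose boxes intersect on the (E, beta) plane."""
        out = []
        for i, a in enumerate(self.ranges):
            for b in self.ranges[i + 1 :]:
                if a.overlaps(b):
                    out.append((a.name, b.name))
        return out

    def to_json(self, path: str | Path) -> None:
        doc = [
            {
                "name": r.name,
                "E_kPa": [r.e_min, r.e_max],
                "beta": [r.beta_min, r.beta_max],
                "color": r.color,
                "priority": r.priority,
            }
            for r in self.ranges
        ]
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassRangeSet":
        doc = json.loads(Path(path).read_text())
        ranges = [
            ClassRange(
                name=item["name"],
                e_min=float(item["E_kPa"][0]),
                e_max=float(item["E_kPa"][1]),
                beta_min=float(item["beta"][0]),
                beta_max=float(item["beta"][1]),
                color=item.get("color", "#808080"),
                priority=int(item["priority"]),
            )
            for item in doc
        ]
        return cls(ranges)


@dataclass
class SegmentationMap:
    """Label map aligned to the elastogram grid plus per-class area fractions.

    ``labels`` holds indices into ``class_names``; ``-1`` is unclassified
    and ``-2`` masked.  ``fractions`` (over all pixels) sums to 1.
    """

    labels: np.ndarray
    class_names: list[str]
    palette: dict[str, str]
    fractions: dict[str, float]

    def label_of(self, name: str) -> int:
        return self.class_names.index(name)

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        # shift so the file holds non-negative integers: 0=masked, 1=unclassified
        tifffile.imwrite(str(path), (self.labels + 2).astype(np.uint8))

    def render_png(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.colors as mcolors
        import matplotlib.pyplot as plt

        colors = ["#FFFFFF", "#BBBBBB"] + [
            self.palette.get(name, "#808080") for name in self.class_names
        ]
        cmap = mcolors.ListedColormap(colors)
        fig, ax = plt.subplots(figsize=(7, 5))
        ax.imshow(self.labels + 2, cmap=cmap, vmin=0, vmax=len(colors) - 1,
                  interpolation="nearest")
        handles = [
            plt.Line2D([], [], marker="s", ls="", color=c, label=n)
            for n, c in zip([MASKED, UNCLASSIFIED] + list(self.class_names), colors)
        ]
        ax.legend(handles=handles, fontsize=6, loc="center left", bbox_to_anchor=(1, 0.5))
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def fractions_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [{"class": k, "area_fraction": v} for k, v in self.fractions.items()]
        ).to_csv(path, index=False)


def calibrate_ranges(
    samples: list[tuple[float, float, str]],
    percentile: float = 2.5,
    margin_frac: float = 0.10,
    min_e_halfwidth_frac: float = 0.05,
    min_beta_halfwidth: float = 0.25,
    palette: dict[str, str] | None = None,
) -> ClassRangeSet:
    """Per-class (E, beta) boxes from labelled calibration samples.

    Each box is the ``[percentile, 100-percentile]`` interval per axis,
    expanded by ``margin_frac`` of its width plus an absolute floor so that
    tight noise-free clusters still get a usable box.  Classes with fewer
    than 3 samples are excluded with a warning.  Priorities default to
    descending ``beta_min`` (the most nonlinear class wins residual
    overlaps deterministically).
    """
    palette = palette or DEFAULT_PALETTE
    by_class: dict[str, list[tuple[float, float]]] = {}
    for E, beta, name in samples:
        if np.isfinite(E) and np.isfinite(beta):
            by_class.setdefault(name, []).append((E, beta))
    boxes = []
    for name, pts in by_class.items():
        if len(pts) < 3:
            log.warning("class %r has %d samples (<3): excluded", name, len(pts))
            continue
        arr = np.asarray(pts)
        e_lo, e_hi = np.percentile(arr[:, 0], [percentile, 100 - percentile])
        b_lo, b_hi = np.percentile(arr[:, 1], [percentile, 100 - percentile])
        e_pad = max(margin_frac * (e_hi - e_lo), min_e_halfwidth_frac * 0.5 * (e_lo + e_hi))
        b_pad = max(margin_frac * (b_hi - b_lo), min_beta_halfwidth)
        boxes.append(
            ClassRange(
                name=name,
                e_min=float(e_lo - e_pad),
                e_max=float(e_hi + e_pad),
                beta_min=float(b_lo - b_pad),
                beta_max=float(b_hi + b_pad),
                color=palette.get(name, "#808080"),
            )
        )
    order = np.argsort([-b.beta_min for b in boxes], kind="stable")
    for rank, idx in enumerate(order):
        boxes[int(idx)].priority = len(boxes) - rank
    ranges = ClassRangeSet(boxes)
    overlaps = ranges.overlap_report()
    if overlaps:
        log.info("calibrated boxes overlap for pairs: %s", overlaps)
    return ranges


def classify_point(E: float, beta: float, ranges: ClassRangeSet) -> str:
    """Label of the highest-priority box containing (E, beta)."""
    if not np.isfinite(E) or not np.isfinite(beta):
        return MASKED
    for r in ranges.by_priority():
        if r.contains(E, beta):
            return r.name
    return UNCLASSIFIED


def segment(pair: ElastogramPair, ranges: ClassRangeSet) -> SegmentationMap:
    """Pixelwise classification of an elastogram pair.

    Deterministic: ties between overlapping boxes go to the higher
    priority.  Area fractions are computed over all pixels and include the
    unclassified and masked fractions.
    """
    E = pair.E_map
    beta = pair.beta_map
    if E.shape != beta.shape:
        raise ValueError("elastogram grids mismatch")
    valid = pair.mask & np.isfinite(E) & np.isfinite(beta)
    labels = np.full(E.shape, -2, dtype=int)
    labels[valid] = -1
    class_names = [r.name for r in ranges]
    # paint lowest priority first so higher priorities overwrite
    for r in sorted(ranges, key=lambda r: r.priority):
        sel = valid & r.contains(E, beta)
        labels[sel] = class_names.index(r.name)
    n_tot = labels.size
    fractions = {name: float(np.sum(labels == i)) / n_tot for i, name in enumerate(class_names)}
    fractions[UNCLASSIFIED] = float(np.sum(labels == -1)) / n_tot
    fractions[MASKED] = float(np.sum(labels == -2)) / n_tot
    palette = {r.name: r.color for r in ranges}
    return SegmentationMap(labels, class_names, palette, fractions)
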