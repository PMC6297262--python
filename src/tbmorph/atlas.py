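"""Atlas ROI overlap tables and change-pattern classification.

Significant clusters, mirrored to both hemispheres, are warped into atlas
space; for each atlas ROI the table reports how many voxels (and what
percentage of the ROI) overlap the expansion and shrinkage masks per interval,
a signed overall percentage combining both intervals, and a pattern label
(reversible vs enduring expansion/shrinkage) driven by a relevance threshold
of 10% of ROI volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .core import LabelVolume, load_labels
from .register import DisplacementField, warp
from .stats import ClusterSet

__all__ = [
    "Atlas",
    "ROIOverlapRow",
    "PATTERN_LABELS",
    "load_atlas",
    "map_clusters_to_atlas",
    "roi_overlap_table",
    "overall_change",
    "classify_pattern",
    "build_roi_report",
    "round_half_up",
]

PATTERN_LABELS = (
    "reversible_expansion",
    "reversible_shrinkage",
    "enduring_shrinkage",
    "enduring_expansion",
    "enduring_fluid_expansion",
    "below_threshold",
    "mixed",
)

UNLABELED = "Unlabeled"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), applied at report time only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Atlas:
    """Label atlas with verified per-ROI voxel volumes and tissue classes."""

    labels: LabelVolume
    roi_volumes: dict[str, int]
    tissue_class: dict[str, str]     # roi -> tissue / csf / white_matter

    @classmethod
    def from_label_volume(cls, labels: LabelVolume,
                          tissue_class: dict[str, str] | None = None) -> "Atlas":
        volumes = labels.roi_voxel_counts()
        tc = dict(tissue_class or {})
        for name in volumes:
            tc.setdefault(name, "tissue")
        return cls(labels=labels, roi_volumes=volumes, tissue_class=tc)

    @property
    def roi_names(self) -> list[str]:
        return [self.labels.lut[k] for k in sorted(self.labels.lut)]


def load_atlas(label_volume_file, lut_file, tissue_class_file=None) -> Atlas:
    """Load a label grid + lookup table (+ optional ROI tissue-class table)
    and verify per-ROI volumes against the grid. Lut entries absent from the
    grid only warn; grid labels absent from the lut are rejected."""
    labels = load_labels(label_volume_file, lut_file)
    present = set(np.unique(labels.labels).tolist()) - {0}
    for lab_id in set(labels.lut) - present:
        warnings.warn(f"atlas lut id {lab_id} ({labels.lut[lab_id]!r}) has no voxels",
                      stacklevel=2)
    classes: dict[str, str] = {}
    if tissue_class_file is not None:
        for line in Path(tissue_class_file).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, cls_ = (line.split("\t") if "\t" in line else line.split(",", 1))
            classes[name.strip()] = cls_.strip()
    return Atlas.from_label_volume(labels, classes)


def map_clusters_to_atlas(clusters: ClusterSet,
                          template_to_atlas: DisplacementField | None,
                          mirror_axis: int | None = 0) -> np.ndarray:
    """Nearest-neighbour warp of the cluster union mask into atlas space,
    after reflecting clusters to both hemispheres (bilateral reporting).
    ``template_to_atlas`` lives on the atlas grid and samples template space;
    None means the grids coincide."""
    cs = clusters.mirrored(mirror_axis) if mirror_axis is not None else clusters
    mask = cs.union_mask()
    if template_to_atlas is None:
        return mask
    if mask.shape != template_to_atlas.shape:
        raise ValueError("cluster geometry does not match the field's atlas grid")
    from .core import ImageVolume
    img = ImageVolume(data=mask.astype(np.float32), spacing=clusters.spacing,
                      affine=clusters.affine)
    return warp(img, template_to_atlas, "nearest").data > 0.5


@dataclass
class ROIOverlapRow:
    """Expand/shrink overlap of one ROI for one interval (raw voxel counts;
    percentages derive from them and are rounded only for reporting)."""

    roi: str
    roi_vol: int
    interval: int
    expand_vol: int
    shrink_vol: int

    @property
    def expand_pct(self) -> float:
        return 100.0 * self.expand_vol / self.roi_vol if self.roi_vol else float("nan")

    @property
    def shrink_pct(self) -> float:
        return 100.0 * self.shrink_vol / self.roi_vol if self.roi_vol else float("nan")


def roi_overlap_table(expand_mask: np.ndarray, shrink_mask: np.ndarray,
                      atlas: Atlas, interval: int) -> list[ROIOverlapRow]:
    """Per-ROI overlap voxel counts with the expansion and shrinkage masks;
    voxels outside every ROI accumulate under "Unlabeled"."""
    grid = atlas.labels.labels
    if expand_mask.shape != grid.shape or shrink_mask.shape != grid.shape:
        raise ValueError("masks must live on the atlas grid")
    rows = []
    for lab_id in sorted(atlas.labels.lut):
        name = atlas.labels.lut[lab_id]
        sel = grid == lab_id
        rows.append(ROIOverlapRow(
            roi=name, roi_vol=atlas.roi_volumes[name], interval=interval,
            expand_vol=int(np.count_nonzero(expand_mask & sel)),
            shrink_vol=int(np.count_nonzero(shrink_mask & sel))))
    bg = grid == 0
    rows.append(ROIOverlapRow(
        roi=UNLABELED, roi_vol=int(bg.sum()), interval=interval,
        expand_vol=int(np.count_nonzero(expand_mask & bg)),
        shrink_vol=int(np.count_nonzero(shrink_mask & bg))))
    return rows


def overall_change(row1: ROIOverlapRow, row2: ROIOverlapRow) -> float:
    """Signed overall percentage across both intervals,
    100 * (e1 - s1 + e2 - s2) / roi_vol, computed from raw voxel counts and
    rounded last (half-up, 2 decimals)."""
    if row1.roi != row2.roi:
        raise ValueError(f"ROI mismatch: {row1.roi!r} vs {row2.roi!r}")
    if row1.roi_vol == 0:
        return float("nan")
    net = row1.expand_vol - row1.shrink_vol + row2.expand_vol - row2.shrink_vol
    return round_half_up(100.0 * net / row1.roi_vol)


def classify_pattern(row1: ROIOverlapRow, row2: ROIOverlapRow, tissue_class: str,
                     threshold_pct: float = 10.0) -> str:
    """Decision table over the two intervals' unrounded percentages at the
    relevance threshold (default 10% of ROI volume)."""
    if row1.roi != row2.roi:
        raise ValueError(f"ROI mismatch: {row1.roi!r} vs {row2.roi!r}")
    e1 = row1.expand_pct >= threshold_pct
    s1 = row1.shrink_pct >= threshold_pct
    e2 = row2.expand_pct >= threshold_pct
    s2 = row2.shrink_pct >= threshold_pct
    if (e1 and s1) or (e2 and s2):
        return "mixed"
    if e1 and s2:
        return "reversible_expansion"
    if s1 and e2:
        return "reversible_shrinkage"
    if s1 and not e2:
        return "enduring_shrinkage"
    if (e1 or e2) and not (s1 or s2):
        return "enduring_fluid_expansion" if tissue_class == "csf" else "enduring_expansion"
    if not (e1 or s1 or e2 or s2):
        return "below_threshold"
    return "mixed"


def build_roi_report(rows1: list[ROIOverlapRow], rows2: list[ROIOverlapRow],
                     atlas: Atlas, threshold_pct: float = 10.0) -> pd.DataFrame:
    """Two-interval table in the standard column order: ROI volume, interval-1
    expand/shrink volumes and percentages, interval-2 likewise, signed overall
    percentage, and the pattern label."""
    by_roi2 = {r.roi: r for r in rows2}
    records = []
    for r1 in rows1:
        r2 = by_roi2[r1.roi]
        tc = atlas.tissue_class.get(r1.roi, "tissue")
        records.append({
            "roi": r1.roi,
            "roi_vol": r1.roi_vol,
            "expand_vol_1": r1.expand_vol,
            "expand_pct_1": round_half_up(r1.expand_pct) if r1.roi_vol else np.nan,
            "shrink_vol_1": r1.shrink_vol,
            "shrink_pct_1": round_half_up(r1.shrink_pct) if r1.roi_vol else np.nan,
            "expand_vol_2": r2.expand_vol,
            "expand_pct_2": round_half_up(r2.expand_pct) if r1.roi_vol else np.nan,
            "shrink_vol_2": r2.shrink_vol,
            "shrink_pct_2": round_half_up(r2.shrink_pct) if r1.roi_vol else np.nan,
            "overall_pct": overall_change(r1, r2),
            "pattern": classify_pattern(r1, r2, tc, threshold_pct),
            "tissue_class": tc,
        })
    return pd.DataFrame.from_records(records)
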