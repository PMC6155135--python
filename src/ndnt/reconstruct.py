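"""Reconstruction stage: per-class volumes, 2D flattening, statistical report.

The report aggregates the per-component database into per-class statistics:
object count, size distribution (mean/stddev of voxel counts) and the mean
minimum intercentroid distance, alongside the full per-object table.
"Average size" means mean voxel count (volume), not equivalent diameter;
intercentroid distances are centroid-to-centroid, population stddev (ddof=0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .identify import ComponentRecord

__all__ = [
    "StatReport",
    "render_class_volumes",
    "flatten_to_2d",
    "nearest_neighbor_distances",
    "build_report",
]


def render_class_volumes(
    labels: np.ndarray, records: Sequence[ComponentRecord]
) -> Dict[str, np.ndarray]:
    """Split a label volume into one volume per assigned class.

    Each output contains exactly that class's components with their
    original ids; the nonzero voxels of all outputs (including any
    "discarded"/"unassigned" classes) partition the input's nonzero voxels.
    """
    labels = np.asarray(labels)
    k = int(labels.max())
    present = set(np.unique(labels[labels > 0]).tolist())
    by_class: Dict[str, List[int]] = {}
    seen = set()
    for rec in records:
        by_class.setdefault(rec.class_label, []).append(rec.id)
        seen.add(rec.id)
    missing = present - seen
    if missing:
        raise ValueError(f"label ids without records: {sorted(missing)[:5]} ...")
    out: Dict[str, np.ndarray] = {}
    for cls, ids in by_class.items():
        keep = np.zeros(k + 1, dtype=bool)
        keep[ids] = True
        out[cls] = np.where(keep[labels], labels, 0)
    return out


def flatten_to_2d(labels: np.ndarray) -> np.ndarray:
    """Collapse a 3D label volume into a single plane (first-hit rule).

    Each (y, x) column takes the id of its nonzero voxel with the lowest z;
    columns with no foreground stay background.  The choice of rule changes
    id assignment where objects stack, but not the binary footprint.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return labels.copy()
    if labels.ndim != 3:
        raise ValueError("expected a 2D or 3D label volume")
    fg = labels > 0
    any_fg = fg.any(axis=0)
    first_z = fg.argmax(axis=0)
    yy, xx = np.indices(labels.shape[1:])
    flat = labels[first_z, yy, xx]
    return np.where(any_fg, flat, 0)


def nearest_neighbor_distances(
    centroids: Sequence[Sequence[float]], spacing: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Distance from each centroid to its nearest other centroid.

    Euclidean in voxel units, or anisotropy-scaled when ``spacing`` gives
    per-axis physical voxel sizes.
    """
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    if spacing is not None:
        pts = pts * np.asarray(spacing, dtype=np.float64)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return dists[:, 1]


def _records_frame(records: Sequence[ComponentRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        nd = len(rec.centroid)
        axes = "zyx"[-nd:]
        row = {"id": rec.id, "class": rec.class_label, "voxel_count": rec.voxel_count}
        for ax, c in zip(axes, rec.centroid):
            row[f"centroid_{ax}"] = c
        for ax, a, b in zip(axes, rec.bbox_min, rec.bbox_max):
            row[f"bbox_min_{ax}"] = a
            row[f"bbox_max_{ax}"] = b
        for ax, o in zip(axes, rec.orientation):
            row[f"orientation_{ax}"] = o
        row["elongation"] = rec.elongation
        row["mean_intensity"] = rec.mean_intensity
        for i, h in enumerate(rec.intensity_histogram):
            row[f"hist_{i}"] = h
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StatReport:
    """Per-class aggregate statistics plus the per-object table."""

    shape: tuple
    spacing: Optional[tuple]
    config_fingerprint: str
    per_class: Dict[str, dict] = field(default_factory=dict)
    records: List[ComponentRecord] = field(default_factory=list)
    metadata: Dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return _records_frame(self.records)

    def to_json(self) -> str:
        payload = {
            "shape": list(self.shape),
            "spacing": None if self.spacing is None else list(self.spacing),
            "config_fingerprint": self.config_fingerprint,
            "metadata": self.metadata,
            "per_class": self.per_class,
            "n_objects": len(self.records),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)

    def filter_region(self, bbox_min: Sequence[int], bbox_max: Sequence[int]) -> "StatReport":
        """Report restricted to objects whose centroid lies inside the box.

        ``bbox_max`` is half-open.  Filtering to the full volume bbox
        reproduces the unfiltered report.
        """
        kept = [
            r
            for r in self.records
            if all(a <= c < b for a, c, b in zip(bbox_min, r.centroid, bbox_max))
        ]
        sub = build_report(kept, self.shape, self.spacing, self.config_fingerprint)
        sub.metadata = dict(self.metadata)
        sub.metadata["region"] = f"{tuple(bbox_min)}..{tuple(bbox_max)}"
        return sub


def build_report(
    records: Sequence[ComponentRecord],
    shape: Sequence[int],
    spacing: Optional[Sequence[float]] = None,
    config_fingerprint: str = "",
) -> StatReport:
    """Compile per-class aggregates from classified component records.

    Components labeled "discarded" are excluded from aggregates (they stay
    out of the per-class map entirely).  Nearest-neighbor statistics are
    reported only for classes with at least two objects.
    """
    report = StatReport(
        shape=tuple(int(s) for s in shape),
        spacing=None if spacing is None else tuple(float(s) for s in spacing),
        config_fingerprint=config_fingerprint,
        records=list(records),
        metadata={"size_definition": "voxel_count", "distance_definition": "centroid_to_centroid"},
    )
    by_class: Dict[str, List[ComponentRecord]] = {}
    for rec in records:
        if rec.class_label == "discarded":
            continue
        by_class.setdefault(rec.class_label, []).append(rec)
    for cls, recs in sorted(by_class.items()):
        sizes = np.array([r.voxel_count for r in recs], dtype=np.float64)
        entry = {
            "object_count": len(recs),
            "mean_size_voxels": float(sizes.mean()),
            "std_size_voxels": float(sizes.std(ddof=0)),
            "mean_min_intercentroid_voxels": None,
            "mean_min_intercentroid_physical": None,
        }
        if len(recs) >= 2:
            cents = [r.centroid for r in recs]
            entry["mean_min_intercentroid_voxels"] = float(
                nearest_neighbor_distances(cents).mean()
            )
            if report.spacing is not None:
                entry["mean_min_intercentroid_physical"] = float(
                    nearest_neighbor_distances(cents, spacing=report.spacing).mean()
                )
        report.per_class[cls] = entry
    return report
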