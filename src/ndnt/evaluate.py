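"""Segmentation quality metrics against ground-truth masks.

Distances are Euclidean in voxel units unless an anisotropic ``spacing``
is given.  Empty-mask conventions: both masks empty -> 0; exactly one
empty -> ``inf`` (an output with no positive voxels is infinitely far from
a nonempty annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricResult",
    "hausdorff",
    "mean_hausdorff",
    "voxel_recall_precision",
    "object_recall",
]


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    meta: dict = field(default_factory=dict)

    def __float__(self):
        return float(self.value)


def _as_mask(a) -> np.ndarray:
    m = np.asarray(a)
    if m.dtype != bool:
        m = m != 0
    return m


def _check_pair(a, b):
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _empty_convention(a, b):
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return float("inf")
    return None


def _distance_to(mask: np.ndarray, spacing) -> np.ndarray:
    """Distance from every voxel to the nearest True voxel of ``mask``."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def hausdorff(a, b, spacing=None, mode: str = "volume") -> MetricResult:
    """Symmetric Hausdorff distance between two binary masks.

    The maximum, over either mask, of the distance to the nearest voxel of
    the other mask; the symmetric value is the larger of the two directed
    maxima.  ``mode="slicewise"`` instead averages the 2D symmetric
    Hausdorff distance over z-slices of a 3D stack (slices empty in both
    masks are skipped).
    """
    a, b = _check_pair(a, b)
    if mode == "slicewise":
        return _slicewise(a, b, spacing, hausdorff, "hausdorff_slicewise")
    if mode != "volume":
        raise ValueError(f"unknown mode {mode!r}")
    sentinel = _empty_convention(a, b)
    if sentinel is not None:
        return MetricResult("hausdorff", sentinel, {"direction": "symmetric"})
    d_ab = _distance_to(b, spacing)[a].max()
    d_ba = _distance_to(a, spacing)[b].max()
    return MetricResult("hausdorff", float(max(d_ab, d_ba)), {"direction": "symmetric"})


def mean_hausdorff(a, b, spacing=None, mode: str = "volume") -> MetricResult:
    """Symmetrized average nearest-voxel distance between two masks.

    The mean over A-voxels of the distance to the nearest B-voxel, averaged
    with the mean over B-voxels of the distance to the nearest A-voxel.
    ``mode="slicewise"`` averages the 2D value over z-slices instead.
    """
    a, b = _check_pair(a, b)
    if mode == "slicewise":
        return _slicewise(a, b, spacing, mean_hausdorff, "mean_hausdorff_slicewise")
    if mode != "volume":
        raise ValueError(f"unknown mode {mode!r}")
    sentinel = _empty_convention(a, b)
    if sentinel is not None:
        return MetricResult("mean_hausdorff", sentinel, {"direction": "symmetric"})
    d_ab = _distance_to(b, spacing)[a].mean()
    d_ba = _distance_to(a, spacing)[b].mean()
    return MetricResult(
        "mean_hausdorff",
        float((d_ab + d_ba) / 2.0),
        {"direction": "symmetric", "definition": "symmetrized average directed distance"},
    )


def _slicewise(a, b, spacing, metric, name):
    if a.ndim != 3:
        raise ValueError("slicewise mode requires 3D masks")
    sp2 = None if spacing is None else tuple(spacing)[1:]
    vals = []
    for z in range(a.shape[0]):
        if not a[z].any() and not b[z].any():
            continue
        vals.append(metric(a[z], b[z], spacing=sp2).value)
    value = 0.0 if not vals else float(np.mean(vals))
    return MetricResult(name, value, {"direction": "symmetric", "n_slices": len(vals)})


def voxel_recall_precision(pred, truth) -> Tuple[Optional[float], Optional[float]]:
    """Voxelwise (recall, precision) of ``pred`` against ``truth``.

    recall = |pred ∧ truth| / |truth|; precision = |pred ∧ truth| / |pred|.
    A 0/0 ratio is reported as None (absent).
    """
    pred, truth = _check_pair(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    n_truth = int(np.count_nonzero(truth))
    n_pred = int(np.count_nonzero(pred))
    recall = None if n_truth == 0 else tp / n_truth
    precision = None if n_pred == 0 else tp / n_pred
    return recall, precision


def object_recall(pred_labels, truth_labels, min_overlap_fraction: float = 0.5) -> float:
    """Fraction of ground-truth objects hit by some predicted object.

    A truth object counts as hit when a single predicted component covers at
    least ``min_overlap_fraction`` of its voxels.
    """
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise ValueError("label volume shapes differ")
    truth_ids, truth_sizes = np.unique(truth[truth > 0], return_counts=True)
    if truth_ids.size == 0:
        raise ValueError("truth contains no objects")
    size_of = dict(zip(truth_ids.tolist(), truth_sizes.tolist()))
    sel = (truth > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([truth[sel], pred[sel]]), axis=1, return_counts=True
    ) if sel.any() else (np.empty((2, 0), dtype=int), np.empty(0, dtype=int))
    hit = set()
    for (t_id, _p_id), c in zip(pairs.T, counts):
        if c >= min_overlap_fraction * size_of[int(t_id)]:
            hit.add(int(t_id))
    return len(hit) / len(truth_ids)
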