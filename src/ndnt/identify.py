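"""Identification stage: cleanup, connected components, stitching, filtering.

Takes the binary mask from segmentation and turns it into labeled
microstructures: small-component removal and binary morphology, connected
component labeling in 3D (or per-slice 2D followed by stitching into 3D
objects), per-component geometric/grayscale descriptors, class assignment
by user-defined filter rules, and cross-channel overlap gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "ComponentRecord",
    "FilterRule",
    "connectivity_structure",
    "morphological_cleanup",
    "label_components",
    "stitch_2d_components",
    "extract_records",
    "classify_components",
    "overlap_filter",
    "keep_largest_components",
]

CONNECTIVITIES = {"face": 1, "face+edge": 2, "full": 3}

_EPS = 1e-12


def connectivity_structure(ndim: int, connectivity: str = "face") -> np.ndarray:
    """Structuring element for the named adjacency.

    "face" is 6-adjacency in 3D (4 in 2D), "face+edge" adds edge neighbors,
    "full" includes corners (26 in 3D, 8 in 2D).
    """
    try:
        order = CONNECTIVITIES[connectivity]
    except KeyError:
        raise ValueError(f"unknown connectivity {connectivity!r}") from None
    return ndimage.generate_binary_structure(ndim, min(order, ndim))


@dataclass
class ComponentRecord:
    """Geometric and grayscale descriptors of one segmented microstructure."""

    id: int
    class_label: str = "unassigned"
    voxel_count: int = 0
    centroid: tuple = ()
    bbox_min: tuple = ()
    bbox_max: tuple = ()  # half-open upper bound per axis
    orientation: tuple = ()  # unit principal axis of the coordinate scatter
    elongation: float = 1.0  # largest / smallest scatter eigenvalue (>= 1)
    mean_intensity: float = 0.0
    intensity_histogram: tuple = ()  # 16 bins, normalized to sum 1

    @property
    def bbox_extents(self) -> tuple:
        return tuple(b - a for a, b in zip(self.bbox_min, self.bbox_max))

    def scalar(self, name: str) -> float:
        """Look up a filterable scalar field by name.

        Supported: voxel_count, mean_intensity, elongation, and
        bbox_extent_<axis> where axis is z/y/x (3D) or y/x (2D) or an
        integer axis index.
        """
        if name in ("voxel_count", "mean_intensity", "elongation"):
            return float(getattr(self, name))
        if name.startswith("bbox_extent_"):
            key = name[len("bbox_extent_"):]
            axes = "zyx"[-len(self.bbox_min):]
            idx = axes.index(key) if key in axes else int(key)
            return float(self.bbox_extents[idx])
        raise KeyError(f"unknown filterable field {name!r}")


@dataclass(frozen=True)
class FilterRule:
    """One classification rule: inclusive ranges over record scalars.

    A record matches when every predicate range contains the record's value.
    Rules are evaluated in order of ``priority`` (lower first); the first
    matching rule assigns its class.
    """

    class_label: str
    predicates: Dict[str, Tuple[float, float]]
    priority: int = 0

    def __post_init__(self):
        for name, (lo, hi) in self.predicates.items():
            if lo > hi:
                raise ValueError(f"rule {self.class_label!r}: range for {name} has lo > hi")

    def matches(self, record: ComponentRecord) -> bool:
        return all(lo <= record.scalar(name) <= hi for name, (lo, hi) in self.predicates.items())


def morphological_cleanup(
    mask: np.ndarray,
    min_size: int = 0,
    ops: Sequence[Tuple[str, int]] = (),
    connectivity: str = "face",
) -> np.ndarray:
    """Remove small components, then run the dilation/erosion schedule.

    ``ops`` is an ordered list of ("dilate", r) / ("erode", r) pairs applied
    with box structuring elements of radius r.  Components smaller than
    ``min_size`` voxels (under ``connectivity``) are removed first.  An
    empty schedule with ``min_size=0`` is the identity.
    """
    out = np.asarray(mask).astype(bool).copy()
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if min_size > 0:
        labels, k = ndimage.label(out, structure=connectivity_structure(out.ndim, connectivity))
        if k:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            out = sizes[labels] >= min_size
    for op, r in ops:
        if r < 1:
            raise ValueError("morphology radius must be >= 1")
        footprint = np.ones((2 * int(r) + 1,) * out.ndim, dtype=bool)
        if op == "dilate":
            out = ndimage.binary_dilation(out, structure=footprint)
        elif op == "erode":
            out = ndimage.binary_erosion(out, structure=footprint)
        else:
            raise ValueError(f"unknown morphology op {op!r}")
    return out


def label_components(mask: np.ndarray, connectivity: str = "face") -> Tuple[np.ndarray, int]:
    """Connected-component labeling; returns (labels, K) with ids 1..K."""
    mask = np.asarray(mask).astype(bool)
    labels, k = ndimage.label(mask, structure=connectivity_structure(mask.ndim, connectivity))
    return labels.astype(np.int32 if k < 2**31 - 1 else np.int64), int(k)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def stitch_2d_components(
    per_slice_labels: Sequence[np.ndarray],
    min_overlap_voxels: int = 1,
    min_overlap_fraction: Optional[float] = None,
) -> Tuple[np.ndarray, int]:
    """Merge per-slice 2D components into 3D objects by footprint overlap.

    Components in adjacent slices sharing at least ``min_overlap_voxels``
    pixels at the same (y, x) positions are merged into one object; merging
    is transitive (union-find).  When ``min_overlap_fraction`` is given, the
    overlap must additionally cover that fraction of the smaller of the two
    component footprints.  Output ids are contiguous 1..K.
    """
    if min_overlap_voxels < 1:
        raise ValueError("min_overlap_voxels must be >= 1")
    slices = [np.asarray(s) for s in per_slice_labels]
    if not slices:
        raise ValueError("no slices given")
    shape2d = slices[0].shape
    if any(s.shape != shape2d for s in slices):
        raise ValueError("all slices must share the same 2D shape")

    # assign provisional global ids: slice-local id -> global id
    offsets = [0]
    for s in slices:
        offsets.append(offsets[-1] + int(s.max()))
    n_global = offsets[-1]
    uf = _UnionFind(n_global + 1)

    global_labels = np.zeros((len(slices),) + shape2d, dtype=np.int64)
    for z, s in enumerate(slices):
        g = np.where(s > 0, s + offsets[z], 0)
        global_labels[z] = g

    sizes = np.bincount(global_labels.ravel(), minlength=n_global + 1)

    for z in range(len(slices) - 1):
        a, b = global_labels[z], global_labels[z + 1]
        sel = (a > 0) & (b > 0)
        if not sel.any():
            continue
        pairs, counts = np.unique(np.stack([a[sel], b[sel]]), axis=1, return_counts=True)
        for (ga, gb), c in zip(pairs.T, counts):
            if c < min_overlap_voxels:
                continue
            if min_overlap_fraction is not None:
                smaller = min(sizes[ga], sizes[gb])
                if c < min_overlap_fraction * smaller:
                    continue
            uf.union(int(ga), int(gb))

    # relabel contiguous in order of first appearance of each root
    root_to_new: Dict[int, int] = {}
    flat = global_labels.ravel()
    remap = np.zeros(n_global + 1, dtype=np.int64)
    for g in range(1, n_global + 1):
        if sizes[g] == 0:
            continue
        r = uf.find(g)
        if r not in root_to_new:
            root_to_new[r] = len(root_to_new) + 1
        remap[g] = root_to_new[r]
    out = remap[flat].reshape(global_labels.shape)
    return out, len(root_to_new)


def _principal_axis(coords: np.ndarray) -> Tuple[tuple, float]:
    """Unit principal axis and elongation of a voxel coordinate cloud.

    Sign convention: the axis is flipped so its first nonzero component
    (z, then y, then x) is nonnegative.  Degenerate scatters (single voxel
    or isotropic point mass) report the first coordinate axis and
    elongation 1; a perfectly flat scatter reports infinite elongation.
    """
    n, d = coords.shape
    if n < 2:
        axis = np.zeros(d)
        axis[0] = 1.0
        return tuple(axis), 1.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    for comp in axis:
        if abs(comp) > _EPS:
            if comp < 0:
                axis = -axis
            break
    lo, hi = float(evals[0]), float(evals[-1])
    if hi <= _EPS:
        elongation = 1.0
    elif lo <= _EPS:
        elongation = float("inf")
    else:
        elongation = hi / lo
    return tuple(float(c) for c in axis), elongation


def extract_records(labels: np.ndarray, source: np.ndarray, n_bins: int = 16) -> List[ComponentRecord]:
    """One :class:`ComponentRecord` per component id in ``labels``.

    ``source`` should be the raw (pre-adjustment) intensity volume so that
    reported intensities are comparable across preprocessing configurations.
    The intensity histogram uses ``n_bins`` equal-width bins spanning the
    global intensity range of ``source``.
    """
    labels = np.asarray(labels)
    source = np.asarray(source)
    if labels.shape != source.shape:
        raise ValueError("labels and source shapes differ")
    k = int(labels.max())
    records: List[ComponentRecord] = []
    if k == 0:
        return records
    lo_edge, hi_edge = float(source.min()), float(source.max())
    if hi_edge <= lo_edge:
        hi_edge = lo_edge + 1.0
    objects = ndimage.find_objects(labels)
    for cid in range(1, k + 1):
        sl = objects[cid - 1]
        assert sl is not None, f"label id {cid} has no voxels"
        region = labels[sl] == cid
        coords = np.argwhere(region) + np.array([s.start for s in sl])
        values = source[sl][region].astype(np.float64)
        hist, _ = np.histogram(values, bins=n_bins, range=(lo_edge, hi_edge))
        hist = hist / hist.sum()
        axis, elong = _principal_axis(coords.astype(np.float64))
        records.append(
            ComponentRecord(
                id=cid,
                voxel_count=int(coords.shape[0]),
                centroid=tuple(float(c) for c in coords.mean(axis=0)),
                bbox_min=tuple(int(c) for c in coords.min(axis=0)),
                bbox_max=tuple(int(c) + 1 for c in coords.max(axis=0)),
                orientation=axis,
                elongation=elong,
                mean_intensity=float(values.mean()),
                intensity_histogram=tuple(float(h) for h in hist),
            )
        )
    return records


def classify_components(
    records: Sequence[ComponentRecord],
    rules: Sequence[FilterRule],
    default: str = "keep_unassigned",
) -> List[ComponentRecord]:
    """Assign each record the class of the first matching rule.

    Rules are tried in increasing priority order.  Records matching no rule
    are labeled "unassigned" (``default="keep_unassigned"``) or "discarded"
    (``default="discard"``); discarded components are excluded from
    per-class reconstruction volumes and report aggregates.
    """
    if default not in ("discard", "keep_unassigned"):
        raise ValueError(f"unknown default policy {default!r}")
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("filter rule priorities must be unique")
    ordered = sorted(rules, key=lambda r: r.priority)
    fallback = "discarded" if default == "discard" else "unassigned"
    for rec in records:
        rec.class_label = fallback
        for rule in ordered:
            if rule.matches(rec):
                rec.class_label = rule.class_label
                break
    return list(records)


def overlap_filter(
    primary_labels: np.ndarray, gate_mask: np.ndarray, min_overlap_voxels: int = 1
) -> Tuple[np.ndarray, int]:
    """Keep components of the primary channel gated by a second channel.

    A component survives when its intersection with ``gate_mask`` contains
    at least ``min_overlap_voxels`` voxels; survivors are relabeled
    contiguously (order of original ids preserved).
    """
    labels = np.asarray(primary_labels)
    gate = np.asarray(gate_mask).astype(bool)
    if labels.shape != gate.shape:
        raise ValueError("primary and gate shapes differ")
    k = int(labels.max())
    overlap = np.bincount(labels[gate].ravel(), minlength=k + 1)
    keep = np.flatnonzero(overlap >= min_overlap_voxels)
    keep = keep[keep > 0]
    remap = np.zeros(k + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels], int(keep.size)


def keep_largest_components(labels: np.ndarray, k: int) -> Tuple[np.ndarray, int]:
    """Retain the k largest components by voxel count (ties: lower id wins)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels)
    n = int(labels.max())
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    sizes[0] = 0
    ids = sorted(range(1, n + 1), key=lambda i: (-sizes[i], i))
    keep = sorted(i for i in ids[:k] if sizes[i] > 0)
    remap = np.zeros(n + 1, dtype=labels.dtype)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    return remap[labels], len(keep)
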