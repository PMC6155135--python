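"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid integral images, distance transforms
and library labeling: neighborhood sums are taken by explicit per-voxel
slicing, Hausdorff distances by pairwise coordinate arithmetic, and
components by flood fill, so they can certify the fast implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from ndnt.core import NDNTParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def brute_neighborhood_stats(vol: np.ndarray, window_shape):
    """Per-voxel clipped box (sum, count) by explicit slicing, no integral image."""
    sums = np.zeros(vol.shape, dtype=np.int64 if np.issubdtype(vol.dtype, np.integer) else np.float64)
    counts = np.zeros(vol.shape, dtype=np.int64)
    for idx in np.ndindex(vol.shape):
        sl = []
        for i, w, n in zip(idx, window_shape, vol.shape):
            lo = max(i - w // 2, 0)
            hi = min(i - w // 2 + w, n)
            sl.append(slice(lo, hi))
        box = vol[tuple(sl)]
        sums[idx] = box.sum()
        counts[idx] = box.size
    return sums, counts


def brute_ndnt(vol: np.ndarray, params: NDNTParams, stats=None):
    """Reference NDNT mask from brute-force neighborhood statistics."""
    sums, counts = brute_neighborhood_stats(vol, params.window_shape) if stats is None else stats
    t = params.threshold_t
    if np.issubdtype(vol.dtype, np.integer) and float(t).is_integer():
        lhs = vol.astype(np.int64) * counts * 100
        if params.polarity == "dark_foreground":
            return lhs <= sums * (100 - int(t))
        return lhs >= sums * (100 + int(t))
    lhs = vol.astype(np.float64) * counts * 100.0
    if params.polarity == "dark_foreground":
        return lhs <= sums * (100.0 - t)
    return lhs >= sums * (100.0 + t)


def brute_prefix_sums(vol: np.ndarray) -> np.ndarray:
    """Triple-loop prefix sums (inclusive), accumulator int64/float64."""
    acc = np.int64 if np.issubdtype(vol.dtype, np.integer) else np.float64
    out = np.zeros(vol.shape, dtype=acc)
    for idx in np.ndindex(vol.shape):
        sl = tuple(slice(0, i + 1) for i in idx)
        out[idx] = vol[sl].sum(dtype=acc)
    return out


def brute_hausdorff(a: np.ndarray, b: np.ndarray, spacing=None, mean=False) -> float:
    """O(|A||B|) pairwise Hausdorff (max or symmetrized-mean variant)."""
    pa = np.argwhere(a).astype(np.float64)
    pb = np.argwhere(b).astype(np.float64)
    if pa.size == 0 and pb.size == 0:
        return 0.0
    if pa.size == 0 or pb.size == 0:
        return float("inf")
    if spacing is not None:
        pa = pa * np.asarray(spacing)
        pb = pb * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    if mean:
        return float((d.min(axis=1).mean() + d.min(axis=0).mean()) / 2.0)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def flood_fill_components(mask: np.ndarray, connectivity: str = "face"):
    """BFS flood-fill labeling; returns (labels, count)."""
    offsets = []
    ndim = mask.ndim
    for off in np.ndindex(*(3,) * ndim):
        d = np.array(off) - 1
        nz = np.count_nonzero(d)
        if nz == 0:
            continue
        if connectivity == "face" and nz > 1:
            continue
        if connectivity == "face+edge" and nz > 2:
            continue
        offsets.append(tuple(d))
    labels = np.zeros(mask.shape, dtype=np.int64)
    k = 0
    for start in np.ndindex(mask.shape):
        if not mask[start] or labels[start]:
            continue
        k += 1
        q = deque([start])
        labels[start] = k
        while q:
            cur = q.popleft()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= c < n for c, n in zip(nb, mask.shape)):
                    if mask[nb] and not labels[nb]:
                        labels[nb] = k
                        q.append(nb)
    return labels, k


def partitions_equal(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """True when two label volumes induce the same partition of foreground."""
    fa, fb = labels_a > 0, labels_b > 0
    if not np.array_equal(fa, fb):
        return False
    a, b = labels_a[fa], labels_b[fb]
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(x for x, _ in pairs)) == len(set(y for _, y in pairs))


def random_mask(rng, shape, density=0.1):
    return rng.random(shape) < density
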