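"""N-dimensional neighborhood thresholding (NDNT) over integral images.

The segmentation primitive of the pipeline: each voxel is compared against
the mean intensity of an axis-aligned box neighborhood centered on it.  The
neighborhood mean is obtained in constant time per voxel from an integral
image (summed-area table) generalized to N dimensions, so the whole volume
is thresholded in a single vectorized pass.

Decision rule, with threshold percentage ``t`` in [0, 100]::

    dark foreground   :  value * count <= window_sum * (100 - t) / 100
    bright foreground :  value * count >= window_sum * (100 + t) / 100

where ``window_sum`` and ``count`` describe the neighborhood box clipped to
the volume bounds.  For integer inputs the comparison is carried out by
cross-multiplication in 64-bit integers, so results are bit-reproducible;
float inputs are compared in double precision.  A window spanning the whole
volume degenerates to a global-mean threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NDNTParams",
    "integral_image",
    "window_sum",
    "ndnt_threshold",
    "ndnt_threshold_2d_stack",
    "ndnt_tiled",
    "threshold_sweep",
]

DARK = "dark_foreground"
BRIGHT = "bright_foreground"


@dataclass(frozen=True)
class NDNTParams:
    """Parameters of the neighborhood threshold.

    Parameters
    ----------
    window_shape : tuple of int
        Per-axis box extents in voxels (length must match the volume's
        dimensionality).  Even extents are centered with the extra voxel on
        the lower-index side.
    threshold_t : float
        Percentage in [0, 100].  ``t = 0`` marks voxels at-or-below
        (dark polarity) or at-or-above (bright) the local mean.
    polarity : {"dark_foreground", "bright_foreground"}
        Which side of the local mean counts as foreground.
    tile_shape : tuple of int, optional
        When set, the volume is partitioned into independent blocks of this
        shape and thresholded per block (independent integral images).
    tile_overlap : tuple of int, optional
        Per-axis overlap between adjacent blocks (default: no overlap).
    """

    window_shape: tuple
    threshold_t: float = 10.0
    polarity: str = DARK
    tile_shape: Optional[tuple] = None
    tile_overlap: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "window_shape", tuple(int(w) for w in self.window_shape))
        if self.tile_shape is not None:
            object.__setattr__(self, "tile_shape", tuple(int(s) for s in self.tile_shape))
        if self.tile_overlap is not None:
            object.__setattr__(self, "tile_overlap", tuple(int(s) for s in self.tile_overlap))
        if not 0.0 <= float(self.threshold_t) <= 100.0:
            raise ValueError(f"threshold_t must lie in [0, 100], got {self.threshold_t}")
        if any(w < 1 for w in self.window_shape):
            raise ValueError(f"window extents must be >= 1, got {self.window_shape}")
        if self.polarity not in (DARK, BRIGHT):
            raise ValueError(f"polarity must be {DARK!r} or {BRIGHT!r}, got {self.polarity!r}")
        if self.tile_shape is not None:
            if len(self.tile_shape) != len(self.window_shape):
                raise ValueError("tile_shape rank must match window_shape rank")
            if any(t < w for t, w in zip(self.tile_shape, self.window_shape)):
                raise ValueError(
                    f"tile extents {self.tile_shape} must be >= window extents {self.window_shape}"
                )

    def validate_for(self, shape: Sequence[int]) -> None:
        if len(self.window_shape) != len(shape):
            raise ValueError(
                f"window rank {len(self.window_shape)} does not match volume rank {len(shape)}"
            )
        if any(w > s for w, s in zip(self.window_shape, shape)):
            raise ValueError(
                f"window {self.window_shape} exceeds volume shape {tuple(shape)} along some axis"
            )


def _accumulator_dtype(a: np.ndarray):
    # Integer (and boolean) volumes are promoted to a 64-bit accumulator so
    # that no integral-image entry can overflow at the volume sizes handled
    # here; floats accumulate in double precision.
    if a.dtype == bool or np.issubdtype(a.dtype, np.integer):
        return np.int64
    return np.float64


def _check_volume(volume: np.ndarray) -> np.ndarray:
    vol = np.asarray(volume)
    if vol.size == 0:
        raise ValueError("empty volume")
    if vol.ndim < 1:
        raise ValueError("volume must have at least one axis")
    if np.issubdtype(vol.dtype, np.floating) and not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite intensities")
    return vol


def integral_image(volume: np.ndarray) -> np.ndarray:
    """Summed-area table of ``volume`` with a zero border.

    Returns an array of shape ``volume.shape + 1`` per axis whose entry at
    index ``i`` (1-based per axis) is the sum of all source voxels with
    coordinates strictly below ``i`` componentwise.  Built by one cumulative
    sum per axis.
    """
    vol = _check_volume(volume)
    acc = _accumulator_dtype(vol)
    out = np.zeros(tuple(s + 1 for s in vol.shape), dtype=acc)
    out[(slice(1, None),) * vol.ndim] = vol
    for ax in range(vol.ndim):
        np.cumsum(out, axis=ax, out=out)
    return out


def _window_bounds(center, window_shape, shape):
    """Clipped half-open [lo, hi) bounds of the box centered at ``center``."""
    lo, hi = [], []
    for c, w, n in zip(center, window_shape, shape):
        a = c - w // 2
        b = a + w
        lo.append(max(a, 0))
        hi.append(min(b, n))
    return tuple(lo), tuple(hi)


def window_sum(integral: np.ndarray, center, window_shape):
    """Exact (sum, count) of the clipped box of ``window_shape`` at ``center``.

    ``integral`` is the zero-bordered table from :func:`integral_image`;
    boundary windows are clipped, so ``count`` may be smaller than the
    nominal window size.
    """
    shape = tuple(s - 1 for s in integral.shape)
    center = tuple(int(c) for c in center)
    if len(center) != len(shape):
        raise ValueError("center rank does not match integral rank")
    if any(not 0 <= c < n for c, n in zip(center, shape)):
        raise IndexError(f"center {center} outside volume of shape {shape}")
    lo, hi = _window_bounds(center, window_shape, shape)
    total = integral.dtype.type(0)
    n = len(shape)
    for bits in itertools.product((0, 1), repeat=n):
        corner = tuple(h if b else l for b, l, h in zip(bits, lo, hi))
        sign = (-1) ** (n - sum(bits))
        total = total + sign * integral[corner]
    count = int(np.prod([h - l for l, h in zip(lo, hi)]))
    return total, count


def _neighborhood_sums(volume: np.ndarray, window_shape):
    """Vectorized clipped-box sums and counts for every voxel."""
    ii = integral_image(volume)
    shape = volume.shape
    n = volume.ndim
    los, his, spans = [], [], []
    for ax, (w, size) in enumerate(zip(window_shape, shape)):
        centers = np.arange(size)
        lo = np.clip(centers - w // 2, 0, size)
        hi = np.clip(centers - w // 2 + w, 0, size)
        los.append(lo)
        his.append(hi)
        spans.append(hi - lo)
    counts = np.ones(shape, dtype=np.int64)
    for ax in range(n):
        sl = [None] * n
        sl[ax] = slice(None)
        counts = counts * spans[ax][tuple(sl)]
    sums = np.zeros(shape, dtype=ii.dtype)
    for bits in itertools.product((0, 1), repeat=n):
        idx = [his[ax] if b else los[ax] for ax, b in enumerate(bits)]
        sign = (-1) ** (n - sum(bits))
        sums += sign * ii[np.ix_(*idx)]
    return sums, counts


def _decide(values, sums, counts, t, polarity):
    """Apply the NDNT decision rule given per-voxel box sums/counts."""
    if np.issubdtype(np.asarray(sums).dtype, np.integer):
        v = values.astype(np.int64)
        lhs = v * counts * 100
        if float(t).is_integer():
            t_int = int(t)
            if polarity == DARK:
                return lhs <= sums * (100 - t_int)
            return lhs >= sums * (100 + t_int)
        # fractional t on integer data: fall through in double precision
        lhs = lhs.astype(np.float64)
        sums = sums.astype(np.float64)
    else:
        lhs = values.astype(np.float64) * counts * 100.0
    if polarity == DARK:
        return lhs <= sums * (100.0 - float(t))
    return lhs >= sums * (100.0 + float(t))


def ndnt_threshold(volume: np.ndarray, params: NDNTParams) -> np.ndarray:
    """Adaptive neighborhood threshold of ``volume``; returns a boolean mask."""
    vol = _check_volume(volume)
    params.validate_for(vol.shape)
    if params.tile_shape is not None:
        return ndnt_tiled(vol, params)
    sums, counts = _neighborhood_sums(vol, params.window_shape)
    return _decide(vol, sums, counts, params.threshold_t, params.polarity)


def ndnt_threshold_2d_stack(volume: np.ndarray, params: NDNTParams) -> np.ndarray:
    """Threshold each z-slice of a 3D stack independently with a 2D window.

    Equivalent to 3D NDNT with window extent 1 along z.
    """
    vol = _check_volume(volume)
    if vol.ndim != 3:
        raise ValueError("ndnt_threshold_2d_stack expects a 3D volume")
    if len(params.window_shape) == 3:
        if params.window_shape[0] != 1:
            raise ValueError("3D window passed to 2D stack thresholding must have z extent 1")
        win2d = params.window_shape[1:]
    elif len(params.window_shape) == 2:
        win2d = params.window_shape
    else:
        raise ValueError("window must be 2D (or 3D with z extent 1)")
    p2 = NDNTParams(window_shape=win2d, threshold_t=params.threshold_t, polarity=params.polarity)
    out = np.empty(vol.shape, dtype=bool)
    for z in range(vol.shape[0]):
        out[z] = ndnt_threshold(vol[z], p2)
    return out


def _tile_starts(size: int, tile: int, overlap: int):
    step = tile - overlap
    if step < 1:
        raise ValueError("tile overlap must be smaller than the tile extent")
    starts = list(range(0, max(size - overlap, 1), step))
    # drop starts that add no new voxels
    return [s for s in starts if s < size]


def ndnt_tiled(volume: np.ndarray, params: NDNTParams) -> np.ndarray:
    """Apply NDNT independently inside blocks of ``params.tile_shape``.

    Each block gets its own integral image; block outputs are placed back
    without blending (later blocks overwrite where blocks overlap).  Blocks
    at the high end of an axis may be smaller than the tile shape; there the
    window is clipped to the block.  With ``tile_shape`` equal to the volume
    shape the result is identical to the untiled threshold.
    """
    vol = _check_volume(volume)
    if params.tile_shape is None:
        raise ValueError("ndnt_tiled requires params.tile_shape")
    if len(params.tile_shape) != vol.ndim:
        raise ValueError("tile rank does not match volume rank")
    overlap = params.tile_overlap or (0,) * vol.ndim
    out = np.zeros(vol.shape, dtype=bool)
    axes_starts = [
        _tile_starts(n, t, o) for n, t, o in zip(vol.shape, params.tile_shape, overlap)
    ]
    for starts in itertools.product(*axes_starts):
        sl = tuple(
            slice(s, min(s + t, n)) for s, t, n in zip(starts, params.tile_shape, vol.shape)
        )
        block = vol[sl]
        win = tuple(min(w, b) for w, b in zip(params.window_shape, block.shape))
        p = NDNTParams(window_shape=win, threshold_t=params.threshold_t, polarity=params.polarity)
        out[sl] = ndnt_threshold(block, p)
    return out


def threshold_sweep(
    volume: np.ndarray,
    params_grid: Sequence[NDNTParams],
    reference: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Grid search over NDNT parameter sets.

    Returns one row per parameter set with the foreground fraction and,
    when a ground-truth ``reference`` mask is given, the mean Hausdorff
    distance between the candidate mask and the reference.  Rows are ordered
    by score ascending (best first), then by ``t`` ascending.
    """
    from .evaluate import mean_hausdorff  # local import to avoid cycle

    if len(params_grid) == 0:
        raise ValueError("params_grid must be nonempty")
    vol = _check_volume(volume)
    if reference is not None and tuple(reference.shape) != tuple(vol.shape):
        raise ValueError("reference shape does not match volume shape")
    rows = []
    for i, p in enumerate(params_grid):
        mask = ndnt_threshold(vol, p)
        row = {
            "index": i,
            "t": float(p.threshold_t),
            "window": p.window_shape,
            "tile": p.tile_shape,
            "polarity": p.polarity,
            "foreground_fraction": float(mask.mean()),
        }
        if reference is not None:
            row["score"] = mean_hausdorff(mask, reference.astype(bool)).value
        rows.append(row)
    df = pd.DataFrame(rows)
    if reference is not None:
        df = df.sort_values(["score", "t"], kind="stable").reset_index(drop=True)
    else:
        df = df.sort_values(["t"], kind="stable").reset_index(drop=True)
    return df
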