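"""Segmentation stage: optional grayscale adjustment followed by NDNT.

Adjustments (histogram equalization, percentile rescaling, Wiener
denoising) run in the order listed in the configuration and output floats
in [0, 1]; the neighborhood threshold then consumes the adjusted volume in
double precision.  With no adjustments the threshold sees the raw volume
(integer comparisons, bit-reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure

from .core import NDNTParams, ndnt_threshold, ndnt_threshold_2d_stack

__all__ = [
    "PreprocessConfig",
    "equalize_histogram",
    "rescale_intensity",
    "wiener_denoise",
    "run_segmentation",
    "global_mean_threshold",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Ordered grayscale adjustments plus the threshold parameters.

    ``steps`` entries are ("histogram_equalization",), ("histogram_rescale",
    lower_percentile, upper_percentile) or ("wiener", window_shape) /
    ("wiener", window_shape, noise_power).  ``mode`` chooses whether the
    threshold (and equalization) run volumetrically or per z-slice.
    """

    ndnt: NDNTParams
    steps: List[tuple] = field(default_factory=list)
    mode: str = "3d"

    def __post_init__(self):
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")


def equalize_histogram(volume: np.ndarray, mode: str = "3d_global") -> np.ndarray:
    """Histogram equalization; output spans [0, 1].

    ``3d_global`` equalizes over the whole volume; ``2d_per_slice``
    equalizes each z-slice independently.  A constant volume has no rank
    structure and is returned unchanged (logged).
    """
    vol = np.asarray(volume)
    if vol.size == 0:
        raise ValueError("empty volume")
    if mode == "3d_global":
        if vol.max() == vol.min():
            log.warning("equalize_histogram: constant volume, returned unchanged")
            return vol.copy()
        return exposure.equalize_hist(vol)
    if mode == "2d_per_slice":
        out = np.empty(vol.shape, dtype=np.float64)
        for z in range(vol.shape[0]):
            sl = vol[z]
            if sl.max() == sl.min():
                log.warning("equalize_histogram: constant slice %d, returned unchanged", z)
                out[z] = sl
            else:
                out[z] = exposure.equalize_hist(sl)
        return out
    raise ValueError(f"unknown equalization mode {mode!r}")


def rescale_intensity(
    volume: np.ndarray, lower_percentile: float, upper_percentile: float
) -> np.ndarray:
    """Linear rescale mapping the given percentiles to [0, 1], clipping outside."""
    if not 0 <= lower_percentile < upper_percentile <= 100:
        raise ValueError("percentiles must satisfy 0 <= lower < upper <= 100")
    vol = np.asarray(volume, dtype=np.float64)
    lo = np.percentile(vol, lower_percentile)
    hi = np.percentile(vol, upper_percentile)
    if hi <= lo:
        raise ValueError("degenerate percentile span (equal intensity values)")
    return np.clip((vol - lo) / (hi - lo), 0.0, 1.0)


def wiener_denoise(
    volume: np.ndarray,
    window_shape: Sequence[int] = None,
    noise_power: Optional[float] = None,
) -> np.ndarray:
    """Local-statistics Wiener denoising.

    output = local_mean + max(0, local_var - noise) / max(local_var, noise)
             * (value - local_mean),
    with ``noise`` defaulting to the mean of the local variances.  Window
    extents must be odd; default 3 per axis.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if window_shape is None:
        window_shape = (3,) * vol.ndim
    window_shape = tuple(int(w) for w in window_shape)
    if any(w < 1 or w % 2 == 0 for w in window_shape):
        raise ValueError("wiener window extents must be odd and >= 1")
    if any(w > s for w, s in zip(window_shape, vol.shape)):
        raise ValueError("wiener window larger than volume")
    # reflective boundaries keep constant regions exactly invariant
    mean = ndimage.uniform_filter(vol, size=window_shape, mode="reflect")
    sq_mean = ndimage.uniform_filter(vol * vol, size=window_shape, mode="reflect")
    var = np.maximum(sq_mean - mean * mean, 0.0)
    noise = float(var.mean()) if noise_power is None else float(noise_power)
    denom = np.maximum(var, noise)
    gain = np.zeros_like(var)
    np.divide(np.maximum(var - noise, 0.0), denom, out=gain, where=denom > 0)
    return mean + gain * (vol - mean)


def _apply_steps(volume: np.ndarray, steps: Sequence[tuple], mode: str) -> np.ndarray:
    out = volume
    for step in steps:
        name = step[0]
        if name == "histogram_equalization":
            out = equalize_histogram(out, "2d_per_slice" if mode == "2d" and out.ndim == 3 else "3d_global")
        elif name == "histogram_rescale":
            out = rescale_intensity(out, step[1], step[2])
        elif name == "wiener":
            out = wiener_denoise(out, *step[1:])
        else:
            raise ValueError(f"unknown preprocessing step {name!r}")
    return out


def global_mean_threshold(
    volume: np.ndarray, t: float = 10.0, polarity: str = "dark_foreground"
) -> np.ndarray:
    """Whole-volume mean threshold: the degenerate case of the local rule.

    Every voxel is compared against the single volume-wide mean with the
    same percentage margin as the neighborhood rule.  This is the
    comparator used to demonstrate the vulnerability of global thresholds
    to grayscale shifts: a neighborhood window grown to the volume size
    behaves globally only at the volume center (windows clip at the
    boundary), so the truly global rule is provided explicitly.
    """
    vol = np.asarray(volume)
    if vol.size == 0:
        raise ValueError("empty volume")
    if vol.dtype == bool or np.issubdtype(vol.dtype, np.integer):
        total = int(vol.sum(dtype=np.int64))
        n = vol.size
        v = vol.astype(np.int64)
        if float(t).is_integer():
            if polarity == "dark_foreground":
                return v * n * 100 <= total * (100 - int(t))
            return v * n * 100 >= total * (100 + int(t))
        v = v.astype(np.float64)
        total = float(total)
    else:
        v = vol.astype(np.float64)
        total = float(v.sum())
        n = vol.size
    if polarity == "dark_foreground":
        return v * n * 100.0 <= total * (100.0 - float(t))
    return v * n * 100.0 >= total * (100.0 + float(t))


def run_segmentation(volume: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Apply the configured adjustments in order, then threshold.

    Returns the binary mask of candidate microstructures.  Deterministic
    for fixed inputs and configuration.
    """
    adjusted = _apply_steps(np.asarray(volume), cfg.steps, cfg.mode)
    if cfg.mode == "2d" and adjusted.ndim == 3:
        return ndnt_threshold_2d_stack(adjusted, cfg.ndnt)
    return ndnt_threshold(adjusted, cfg.ndnt)
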