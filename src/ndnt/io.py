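"""Volume readers and writers: TIFF stacks, numbered image sequences, HDF5.

Volumes are (z, y, x) arrays with the z axis following the stack/sequence
order; image-sequence slices are ordered by the natural numeric order of
their filenames (img_2 before img_10).  Round-trips are bitwise exact;
label volumes are written as the narrowest unsigned integer type that
holds the largest id.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_volume", "write_volume", "natural_sort_key", "label_dtype"]

_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(name: str):
    """Sort key splitting digit runs so img_2 orders before img_10."""
    return [int(p) if p.isdigit() else p for p in _NUM_RE.split(str(name))]


def label_dtype(max_label: int) -> np.dtype:
    """Narrowest unsigned dtype holding ``max_label`` (promotes past 65535)."""
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValueError("label count exceeds uint64 range")


def read_volume(path, fmt: str = "tiff_stack", dataset: Optional[str] = None) -> np.ndarray:
    """Read a grayscale volume as a (z, y, x) array, dtype preserved.

    ``fmt`` is one of ``tiff_stack`` (multi-page TIFF), ``image_sequence``
    (a directory of numbered PNG/TIFF slices) or ``hdf5`` (requires
    ``dataset``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tiff_stack":
        return _as_stack(tifffile.imread(path))
    if fmt == "image_sequence":
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
            key=lambda p: natural_sort_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no image slices in {path}")
        slices = [iio.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes in sequence: {sorted(shapes)}")
        return np.stack(slices, axis=0)
    if fmt == "hdf5":
        if dataset is None:
            raise ValueError("hdf5 format requires a dataset name")
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not in {path}")
            return f[dataset][()]
    raise ValueError(f"unknown volume format {fmt!r}")


def _as_stack(vol: np.ndarray) -> np.ndarray:
    if vol.ndim == 2:
        return vol[None, ...]
    if vol.ndim != 3:
        raise ValueError(f"expected a 2D/3D grayscale TIFF, got shape {vol.shape}")
    return vol


def write_volume(
    array: np.ndarray,
    path,
    fmt: str = "tiff_stack",
    dataset: str = "volume",
    is_labels: bool = False,
) -> None:
    """Write a volume or label volume; round-trip safe.

    Label volumes are cast to the narrowest unsigned type that holds the
    maximum id.  ``image_sequence`` writes one numbered file per z-slice
    into the directory ``path``.
    """
    arr = np.asarray(array)
    if is_labels:
        arr = arr.astype(label_dtype(int(arr.max(initial=0))))
    path = Path(path)
    if fmt == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        # grayscale stacks always; otherwise 3-slice stacks round-trip as RGB
        tifffile.imwrite(path, arr, photometric="minisblack")
        return
    if fmt == "image_sequence":
        path.mkdir(parents=True, exist_ok=True)
        stack = arr if arr.ndim == 3 else arr[None, ...]
        width = max(4, len(str(stack.shape[0])))
        for z in range(stack.shape[0]):
            iio.imwrite(path / f"slice_{z:0{width}d}.tiff", stack[z])
        return
    if fmt == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            f.create_dataset(dataset, data=arr)
        return
    raise ValueError(f"unknown volume format {fmt!r}")
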