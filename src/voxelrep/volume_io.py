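"""Reading, writing and relabelling of 3D volumes and label masks.

Conventions used throughout the package:

* axis order is ``(depth, height, width)``, 0-based;
* intensities are min-max normalized to [0, 1] on load (a constant
  volume maps to all zeros);
* label 0 is reserved for the residual "unrecognized" class.

Supported containers: multi-page TIFF, HDF5 (default dataset keys
``volume`` / ``labels``) and Zarr with the same keys.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
import zarr

__all__ = [
    "Volume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "merge_reference_masks",
    "coarsen_labels",
]

UNRECOGNIZED = "unrecognized"

_TIFF_EXT = (".tif", ".tiff")
_HDF5_EXT = (".h5", ".hdf5", ".hdf")
_ZARR_EXT = (".zarr",)


@dataclass
class Volume:
    """A 3D scalar field with isotropic voxel spacing.

    ``data`` is depth x height x width; intensities are expected in
    [0, 1] (use :func:`normalize` or :func:`read_volume`).
    """

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer class labels, one per voxel, with optional class names.

    ``class_names[k]`` names label ``k``; index 0 is the residual
    "unrecognized" class.
    """

    data: np.ndarray
    class_names: list[str] | None = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume data must be integer-typed")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self):
        return self.data.shape


def normalize(data: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant array maps to zeros."""
    data = np.asarray(data, dtype=np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def _kind(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _TIFF_EXT:
        return "tiff"
    if ext in _HDF5_EXT:
        return "hdf5"
    if ext in _ZARR_EXT or os.path.isdir(path):
        return "zarr"
    raise ValueError(
        f"unknown volume format {ext!r}; supported: TIFF {_TIFF_EXT}, "
        f"HDF5 {_HDF5_EXT}, Zarr {_ZARR_EXT}")


def _read_array(path: str, dataset_key: str) -> np.ndarray:
    kind = _kind(path)
    if kind == "tiff":
        return np.asarray(tifffile.imread(path))
    if kind == "hdf5":
        with h5py.File(path, "r") as f:
            key = dataset_key if dataset_key in f else next(iter(f))
            return f[key][()]
    root = zarr.open_group(path, mode="r")
    key = dataset_key if dataset_key in root else next(iter(root.array_keys()))
    return root[key][()]


def _write_array(path: str, data: np.ndarray, dataset_key: str) -> None:
    kind = _kind(path)
    if kind == "tiff":
        tifffile.imwrite(path, data)
    elif kind == "hdf5":
        with h5py.File(path, "a") as f:
            if dataset_key in f:
                del f[dataset_key]
            f.create_dataset(dataset_key, data=data)
    else:
        root = zarr.open_group(path, mode="a")
        if dataset_key in root:
            del root[dataset_key]
        root.create_array(dataset_key, shape=data.shape, dtype=data.dtype)
        root[dataset_key][:] = data


def read_volume(path: str, dataset_key: str = "volume") -> Volume:
    """Load a 3D intensity volume, normalized to [0, 1].

    Parameters
    ----------
    path
        TIFF stack, HDF5 file or Zarr store.
    dataset_key
        Dataset name for HDF5/Zarr; if absent, the first dataset in the
        file is used. Ignored for TIFF.
    """
    data = _read_array(path, dataset_key)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data in {path}, got shape {data.shape}")
    return Volume(normalize(data))


def write_volume(volume: Volume, path: str, dataset_key: str = "volume") -> None:
    _write_array(path, np.asarray(volume.data, dtype=np.float32), dataset_key)


def read_labels(path: str, dataset_key: str = "labels",
                class_names: list[str] | None = None) -> LabelVolume:
    data = _read_array(path, dataset_key)
    if data.ndim != 3:
        raise ValueError(f"expected 3D labels in {path}, got shape {data.shape}")
    return LabelVolume(data.astype(np.int64), class_names=class_names)


def write_labels(labels: LabelVolume, path: str, dataset_key: str = "labels") -> None:
    data = labels.data
    if data.max() <= np.iinfo(np.uint8).max:
        data = data.astype(np.uint8)
    _write_array(path, data, dataset_key)


def merge_reference_masks(
    masks: list[tuple[str, np.ndarray]],
    priority: list[str],
) -> LabelVolume:
    """Merge per-class binary masks into a single label volume.

    Where masks overlap, the class earliest in ``priority`` wins
    (curated annotation prevails over automated masks). Voxels covered
    by no mask receive label 0, "unrecognized". Output labels follow the
    order of ``masks`` (first mask -> label 1, and so on).
    """
    if not masks:
        raise ValueError("no masks provided")
    names = [name for name, _ in masks]
    missing = [n for n in names if n not in priority]
    if missing:
        raise ValueError(f"priority list is missing classes: {missing}")
    shape = np.asarray(masks[0][1]).shape
    for name, m in masks:
        if np.asarray(m).shape != shape:
            raise ValueError(
                f"mask {name!r} has shape {np.asarray(m).shape}, expected {shape}")

    out = np.zeros(shape, dtype=np.int64)
    # paint in reverse priority so that higher-priority classes overwrite
    rank = {n: i for i, n in enumerate(priority)}
    for name, mask in sorted(masks, key=lambda nm: rank[nm[0]], reverse=True):
        label = names.index(name) + 1
        out[np.asarray(mask).astype(bool)] = label
    return LabelVolume(out, class_names=[UNRECOGNIZED] + names)


def coarsen_labels(labels: LabelVolume, major: list[str]) -> LabelVolume:
    """Merge all classes outside ``major`` into "unrecognized" (label 0).

    The evaluation protocol keeps only the large classes (by default
    nucleus, granule and mitochondria) and folds every minor class into
    the residual, so the reference has ``1 + len(major)`` classes.
    """
    if not major:
        raise ValueError("major class list is empty")
    if labels.class_names is None:
        raise ValueError("labels have no class names to coarsen by")
    unknown = [m for m in major if m not in labels.class_names]
    if unknown:
        raise ValueError(f"classes not present in labels: {unknown}")

    lut = np.zeros(len(labels.class_names), dtype=np.int64)
    kept = [n for n in labels.class_names if n in major and n != UNRECOGNIZED]
    for new_label, name in enumerate(kept, start=1):
        lut[labels.class_names.index(name)] = new_label
    return LabelVolume(lut[labels.data], class_names=[UNRECOGNIZED] + kept)
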