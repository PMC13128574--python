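"""Volume I/O: HDF5 datasets and multipage TIFF stacks."""

from __future__ import annotations

import os

import h5py
import numpy as np
import tifffile

from .exceptions import ConfigurationError

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels"]

DEFAULT_DATASET = "main"


def _is_tiff(path: str) -> bool:
    return os.path.splitext(path)[1].lower() in (".tif", ".tiff")


def read_volume(path: str, dataset: str = DEFAULT_DATASET) -> np.ndarray:
    """Read a 3D volume from HDF5 (named dataset) or a multipage TIFF."""
    if _is_tiff(path):
        return np.asarray(tifffile.imread(path))
    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise ConfigurationError(
                f"dataset {dataset!r} not found in {path}; available: {list(f)}")
        return f[dataset][()]


def write_volume(path: str, data: np.ndarray, dataset: str = DEFAULT_DATASET) -> None:
    """Write a 3D volume to HDF5 or multipage TIFF (by file extension)."""
    if _is_tiff(path):
        tifffile.imwrite(path, np.asarray(data))
        return
    mode = "a" if os.path.exists(path) else "w"
    with h5py.File(path, mode) as f:
        if dataset in f:
            del f[dataset]
        f.create_dataset(dataset, data=np.asarray(data), compression="gzip")


def read_labels(path: str, dataset: str = "labels") -> np.ndarray:
    return np.asarray(read_volume(path, dataset)).astype(np.int64)


def write_labels(path: str, labels: np.ndarray, dataset: str = "labels") -> None:
    write_volume(path, np.asarray(labels).astype(np.uint32), dataset)
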