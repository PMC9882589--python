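"""Readers and writers for the on-disk formats.

K-space travels in HDF5 (datasets ``/kspace`` complex64, ``/te_ms``,
``/mask``); magnitude images and T2 maps in NIfTI with the echo (or a
singleton) as the third axis and an identity affine for synthetic data.
Precision contract: float64/complex128 in memory, float32/complex64 on disk.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .types import ImageSeries, KSpaceSeries, T2Map

__all__ = [
    "read_kspace",
    "write_kspace",
    "read_image",
    "write_image",
    "write_t2map",
    "read_t2map",
]


def write_kspace(ks: KSpaceSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=ks.data.astype(np.complex64))
        h5.create_dataset("te_ms", data=ks.te.astype(np.float64))
        h5.create_dataset("mask", data=ks.mask.astype(np.uint8))


def read_kspace(path: str | Path) -> KSpaceSeries:
    with h5py.File(path, "r") as h5:
        for name in ("kspace", "te_ms", "mask"):
            if name not in h5:
                raise KeyError(f"HDF5 container is missing dataset /{name}")
        data = np.asarray(h5["kspace"], dtype=complex)
        te = np.asarray(h5["te_ms"], dtype=float)
        mask = np.asarray(h5["mask"]).astype(bool)  # tolerant of {0,1} ints
    return KSpaceSeries(data=data, te=te, mask=mask)


def _to_volume(data: np.ndarray) -> np.ndarray:
    if data.ndim == 2:
        data = data[None]
    # NIfTI convention: spatial axes first, echo last
    return np.moveaxis(data, 0, -1).astype(np.float32)


def write_image(f: ImageSeries | np.ndarray, path: str | Path) -> None:
    data = f.data if isinstance(f, ImageSeries) else np.asarray(f, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite voxel values")
    img = nib.Nifti1Image(_to_volume(data), affine=np.eye(4))
    nib.save(img, str(path))


def read_image(path: str | Path, te: np.ndarray | None = None):
    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    data = np.moveaxis(vol, -1, 0)
    if te is None:
        return data
    return ImageSeries(data=np.clip(data, 0, None), te=te)


def write_t2map(t2: T2Map, path: str | Path) -> None:
    write_image(t2.data[None], path)


def read_t2map(path: str | Path) -> T2Map:
    data = read_image(path)
    return T2Map(data=np.maximum(data[0], np.finfo(np.float32).tiny))
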