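"""NIfTI and table I/O helpers.

Volumes are written as NIfTI-1 with the voxel size encoded in a diagonal
affine; tables are tab-separated with a header row.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from dnqsm.containers import as_voxel_size

__all__ = ["save_nifti", "load_nifti", "save_table", "load_table", "file_sha256"]


def save_nifti(data: np.ndarray, voxel_size_mm, path) -> Path:
    v = as_voxel_size(voxel_size_mm)
    affine = np.diag([v[0], v[1], v[2], 1.0])
    data = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(data, affine)
    zooms = tuple(v) + (1.0,) * (data.ndim - 3)
    img.header.set_zooms(zooms)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path):
    """Return (data, voxel_size_mm) from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    voxel = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, voxel


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
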