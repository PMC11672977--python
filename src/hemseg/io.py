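"""NIfTI reading/writing and sidecar serialization.

In-memory arrays follow the ``(slice, row, column)`` convention; on disk the
NIfTI data block is stored ``(column, row, slice)`` with a diagonal affine
carrying the voxel spacing, so files round-trip exactly and are readable by
standard viewers.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import CTVolume

__all__ = ["load_ct", "save_nifti", "load_labels"]


def save_nifti(voxels: np.ndarray, spacing, path: str | Path) -> None:
    """Write a (slice, row, col) array with the given mm spacing."""
    voxels = np.asarray(voxels)
    data = np.ascontiguousarray(voxels.transpose(2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _read(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got rank {data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return data.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def load_ct(path: str | Path) -> CTVolume:
    voxels, spacing = _read(path)
    return CTVolume(voxels.astype(np.float32), spacing)


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    voxels, spacing = _read(path)
    return np.rint(voxels).astype(np.uint8), spacing
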