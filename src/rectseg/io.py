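"""Volume and manifest I/O.

Volumes are exchanged as NIfTI-1 files: images as float32, label maps as
uint8, with the voxel spacing carried in the header zooms.  The coordinate
convention throughout the package is deliberately simple: voxel indices are
0-based and physical coordinates are ``index * spacing`` — no orientation
matrix beyond a diagonal affine is read or written.

Cohort manifests are plain CSV with one row per case:
``case_id, image_path, label_path, split, spec_id, seed``.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["case_id", "image_path", "label_path", "split", "spec_id", "seed"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path: str, data: np.ndarray, spacing) -> None:
    """Write a 3D volume to NIfTI-1 with a diagonal affine from *spacing*."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer) or data.dtype == np.bool_:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, path)


def read_volume(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, spacing-in-mm)."""
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_manifest(path: str, manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return manifest


def resolve_path(manifest_path: str, p: str) -> str:
    """Resolve a manifest-relative path against the manifest's directory."""
    if os.path.isabs(p):
        return p
    return os.path.join(os.path.dirname(os.path.abspath(manifest_path)), p)
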