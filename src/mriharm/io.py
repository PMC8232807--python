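"""NIfTI / CSV / YAML serialization helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ImageVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "write_feature_table",
    "read_feature_table",
    "write_manifest",
    "read_manifest",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(path, subject_id: str = "") -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(
        values=np.asarray(img.get_fdata(), dtype=np.float64),
        spacing=spacing,
        subject_id=subject_id,
    )


def save_mask(mask: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


def write_feature_table(table: pd.DataFrame, path) -> None:
    """CSV with numeric fields rounded to 12 significant digits (reproducible)."""
    out = table.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: float(f"{v:.12g}"))
    out.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
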