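"""Per-ROI feature vectors and study-level feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import ImageVolume, ROISet
from .discretize import discretize_fixed_bin_number
from .firstorder import first_order_features
from .registry import FEATURE_NAMES
from .texture import (
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["extract_all_features", "extract_feature_table"]

ID_COLUMNS = ["study_id", "subject_id", "setting_id", "tissue_class", "roi_id"]


def _roi_plane(mask: np.ndarray) -> tuple[int, int]:
    """Axis and index of the single plane containing the 2D ROI."""
    idx = np.nonzero(mask)
    for axis in range(3):
        vals = np.unique(idx[axis])
        if vals.size == 1:
            return axis, int(vals[0])
    raise ValueError("ROI is not confined to a single plane (2D ROIs required)")


def extract_all_features(
    volume: ImageVolume, mask: np.ndarray, n_bins: int = 32
) -> dict[str, float]:
    """All 92 features of one single-slice ROI.

    Texture matrices are built on the in-plane 2D grid of the ROI's
    slice; a constant ROI yields finite values everywhere through the
    documented degenerate-case conventions.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    axis, plane = _roi_plane(mask)
    sl = [slice(None)] * 3
    sl[axis] = plane
    values2d = volume.values[tuple(sl)]
    mask2d = mask[tuple(sl)]

    disc = discretize_fixed_bin_number(values2d, mask2d, n_bins=n_bins)
    voxel_volume = float(np.prod(volume.spacing))

    out: dict[str, float] = {}
    for fam, feats in (
        ("firstorder", first_order_features(disc, voxel_volume)),
        ("glcm", glcm_features(disc)),
        ("glrlm", glrlm_features(disc)),
        ("glszm", glszm_features(disc)),
        ("ngtdm", ngtdm_features(disc)),
        ("gldm", gldm_features(disc)),
    ):
        for name, value in feats.items():
            out[f"{fam}_{name}"] = value

    out = {name: out[name] for name in FEATURE_NAMES}
    assert len(out) == 92
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite features: {bad}")
    return out


def extract_feature_table(
    volume: ImageVolume,
    rois: ROISet,
    study_id: str = "study",
    n_bins: int = 32,
) -> pd.DataFrame:
    """Feature table for all ROIs of one acquisition.

    Rows are (study, subject, setting, tissue class, roi); columns are
    the id columns followed by the 92 ``family_FeatureName`` columns.
    """
    setting_id = volume.setting.setting_id if volume.setting else "unknown"
    rows = []
    for roi in rois:
        feats = extract_all_features(volume, roi.mask, n_bins=n_bins)
        rows.append(
            {
                "study_id": study_id,
                "subject_id": volume.subject_id,
                "setting_id": setting_id,
                "tissue_class": roi.tissue_class,
                "roi_id": roi.roi_id,
                **feats,
            }
        )
    return pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)
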