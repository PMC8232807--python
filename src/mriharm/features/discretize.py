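"""Fixed-bin-number (FBN) discretization of ROI intensities.

FBN quantizes the ROI's own min-max range into ``n_bins`` equal-width
bins, so the discretized levels — and therefore all texture features —
are invariant to positive affine transforms of the ROI intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "discretize_fixed_bin_number"]


@dataclass
class DiscretizedROI:
    """Discretized 2D ROI: levels in {1..n_bins} inside the mask, 0 outside."""

    levels: np.ndarray  # int grid, 0 marks outside-ROI pixels
    mask: np.ndarray
    n_bins: int
    values: np.ndarray  # original real grid
    edges: np.ndarray

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def roi_values(self) -> np.ndarray:
        return self.values[self.mask]


def discretize_fixed_bin_number(
    values: np.ndarray, mask: np.ndarray | None = None, n_bins: int = 32
) -> DiscretizedROI:
    """Discretize ROI pixels into ``n_bins`` equal-width levels.

    level(x) = 1 + floor(n_bins * (x - min) / (max - min)), with the
    maximum value assigned level ``n_bins``.  A constant ROI maps to
    level 1 everywhere.
    """
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    roi = values[mask]
    mn, mx = roi.min(), roi.max()
    edges = np.linspace(mn, mx, n_bins + 1)
    levels = np.zeros(values.shape, dtype=np.int64)
    if mx > mn:
        lv = 1 + np.floor(n_bins * (roi - mn) / (mx - mn)).astype(np.int64)
        np.clip(lv, 1, n_bins, out=lv)
    else:
        lv = np.ones(roi.shape, dtype=np.int64)
    levels[mask] = lv
    return DiscretizedROI(levels=levels, mask=mask, n_bins=n_bins, values=values, edges=edges)
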