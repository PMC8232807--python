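"""Core domain containers for synthetic multi-setting MRI studies.

An acquisition *setting* bundles the scanner-side knobs that generate a
scanner effect (global gain/offset, smooth multiplicative bias field,
noise level, and the FOV/matrix pair that fixes in-plane voxel spacing).
Volumes, ROI masks and settings are plain dataclasses over numpy arrays;
NIfTI serialization lives in :mod:`mriharm.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionSetting",
    "ImageVolume",
    "ROIMask",
    "ROISet",
]


@dataclass(frozen=True)
class AcquisitionSetting:
    """One scanner configuration.

    ``field_strength`` is an informational label (Tesla); the actual effect
    on intensities is carried by ``gain``, ``offset``, ``bias_amplitude``
    and ``noise_sigma``.  In-plane voxel spacing is derived from the
    FOV (cm) and acquisition matrix: ``fov * 10 / matrix`` mm.
    """

    setting_id: str
    field_strength: float = 1.5
    fov: float = 24.0
    matrix: int = 256
    gain: float = 1.0
    offset: float = 0.0
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.fov <= 0:
            raise ValueError(f"fov must be positive, got {self.fov}")
        if self.matrix < 8:
            raise ValueError(f"matrix must be >= 8, got {self.matrix}")
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.bias_amplitude <= 0.9:
            raise ValueError("bias_amplitude must lie in [0, 0.9]")

    @property
    def inplane_spacing(self) -> float:
        """In-plane voxel spacing in mm (FOV is in cm)."""
        return self.fov * 10.0 / self.matrix


@dataclass
class ImageVolume:
    """A 3D intensity grid with voxel spacing in mm.

    Axis convention: axes (0, 1) are in-plane (transverse); axis 2 is the
    slice axis.  Sagittal planes are slices along axis 0.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    setting: AcquisitionSetting | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray, **kw) -> "ImageVolume":
        return ImageVolume(
            values=values,
            spacing=kw.get("spacing", self.spacing),
            setting=kw.get("setting", self.setting),
            subject_id=kw.get("subject_id", self.subject_id),
        )


@dataclass
class ROIMask:
    """One labelled region: a boolean grid aligned to its volume."""

    tissue_class: str
    roi_id: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.roi_id} ({self.tissue_class}) is empty")

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class ROISet:
    """Labelled masks aligned to one volume.

    Masks within a tissue class are disjoint.  For paired settings at equal
    spacing the corresponding masks are voxel-identical, so any feature
    difference is attributable to the injected scanner effect alone.
    """

    masks: list[ROIMask] = field(default_factory=list)
    plane: str = "transverse"

    def __iter__(self):
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def by_class(self, tissue_class: str) -> list[ROIMask]:
        return [m for m in self.masks if m.tissue_class == tissue_class]

    @property
    def tissue_classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.masks:
            seen.setdefault(m.tissue_class, None)
        return list(seen)

    def validate_against(self, volume: ImageVolume) -> None:
        """Check masks fit the volume and are disjoint within each class."""
        for m in self.masks:
            if m.mask.shape != volume.shape:
                raise ValueError(
                    f"ROI {m.roi_id} shape {m.mask.shape} does not match "
                    f"volume shape {volume.shape}"
                )
        for cls in self.tissue_classes:
            total = np.zeros(volume.shape, dtype=np.int32)
            for m in self.by_class(cls):
                total += m.mask
            if (total > 1).any():
                raise ValueError(f"overlapping ROIs within tissue class {cls!r}")


def check_paired_rois(a: ROISet, b: ROISet) -> bool:
    """True when two ROI sets are voxel-identical mask for mask."""
    if len(a) != len(b):
        return False
    return all(
        ma.tissue_class == mb.tissue_class
        and ma.roi_id == mb.roi_id
        and ma.mask.shape == mb.mask.shape
        and np.array_equal(ma.mask, mb.mask)
        for ma, mb in zip(a.masks, b.masks)
    )
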