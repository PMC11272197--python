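"""Core in-memory containers: axial image stacks and aligned binary masks.

Conventions
-----------
* Voxel arrays are ``(n_slices, rows, cols)``; slice index 0 is the most
  caudal slice (the acquisition starts at S1-L5 and proceeds proximally),
  so 1-based user-facing slice numbers count caudal -> cranial.
* Geometry is always explicit: in-plane pixel spacing (row, col) in mm and
  slice thickness in mm.  There are no silent geometry defaults anywhere in
  the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["ImageStack", "MaskStack"]


@dataclass
class ImageStack:
    """An ordered stack of axial T1 slices with physical geometry.

    Parameters
    ----------
    voxels
        Float array ``(n_slices, rows, cols)`` of non-negative intensities.
    pixel_spacing_mm
        In-plane (row, col) spacing in millimetres.
    slice_thickness_mm
        Slice thickness in millimetres.
    normalized
        Provenance flag: True once the stack has passed through intensity
        normalization.  Normalization of an already-normalized stack is a
        no-op, which makes the operation idempotent by construction.
    metadata
        Free-form acquisition metadata (e.g. TR/TE), carried but unused.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ConfigurationError(
                f"voxels: expected a 3-D (n_slices, rows, cols) array, got ndim={self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ConfigurationError("voxels: intensities must be finite")
        if np.any(self.voxels < 0):
            raise ConfigurationError("voxels: intensities must be non-negative")
        rs, cs = self.pixel_spacing_mm
        if rs <= 0 or cs <= 0 or self.slice_thickness_mm <= 0:
            raise ConfigurationError(
                "pixel_spacing_mm/slice_thickness_mm: all spacings must be strictly positive"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        rs, cs = self.pixel_spacing_mm
        return float(rs * cs * self.slice_thickness_mm)

    def copy(self) -> "ImageStack":
        return replace(self, voxels=self.voxels.copy(), metadata=dict(self.metadata))


@dataclass
class MaskStack:
    """Binary labels aligned voxel-for-voxel with an :class:`ImageStack`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ConfigurationError(
                f"labels: expected a 3-D (n_slices, rows, cols) array, got ndim={arr.ndim}"
            )
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ConfigurationError("labels: values must be binary (0/1)")
            arr = arr.astype(bool)
        self.labels = arr

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_count(self) -> int:
        return int(self.labels.sum())

    def copy(self) -> "MaskStack":
        return MaskStack(self.labels.copy())

    def __and__(self, other: "MaskStack") -> "MaskStack":
        return MaskStack(self.labels & other.labels)

    def __or__(self, other: "MaskStack") -> "MaskStack":
        return MaskStack(self.labels | other.labels)

    def __invert__(self) -> "MaskStack":
        return MaskStack(~self.labels)

    def is_subset_of(self, other: "MaskStack") -> bool:
        return bool(np.all(~self.labels | other.labels))

    def is_disjoint_from(self, other: "MaskStack") -> bool:
        return not bool(np.any(self.labels & other.labels))


def dice(a: MaskStack | np.ndarray, b: MaskStack | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); defined as 1.0 for two empty masks."""
    aa = a.labels if isinstance(a, MaskStack) else np.asarray(a, bool)
    bb = b.labels if isinstance(b, MaskStack) else np.asarray(b, bool)
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(aa, bb).sum() / denom)


__all__.append("dice")
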