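"""Compartment volumes over a slice window and the VAT/SAT ratio.

Volumes are pure voxel counting: a voxel is all-or-nothing (the masks are
binary), and voxel volume is row_spacing x col_spacing x slice_thickness.
The default analysis window is slices 4..11 (1-based, caudal -> cranial),
i.e. eight slices of a 22-slice acquisition; both the SAT and VAT volumes
— and hence the ratio — are restricted to the same window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError
from .segmentation import SegmentationResult
from .types import ImageStack

__all__ = ["VolumeReport", "compute_volumes", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = (4, 11)


@dataclass
class VolumeReport:
    """Window-restricted compartment volumes for one subject.

    ``vat_sat_ratio`` is ``None`` (undefined) when the SAT volume is zero;
    no division error is ever raised.
    """

    sat_cm3: float
    vat_cm3: float
    vat_sat_ratio: float | None
    slice_window: tuple[int, int]
    voxel_volume_mm3: float
    per_slice_breakdown: pd.DataFrame  # columns: slice, sat_voxels, vat_voxels, sat_cm3, vat_cm3

    @property
    def ratio_defined(self) -> bool:
        return self.vat_sat_ratio is not None

    def to_record(self) -> dict:
        return {
            "sat_cm3": self.sat_cm3,
            "vat_cm3": self.vat_cm3,
            "vat_sat_ratio": self.vat_sat_ratio,
            "window_first": self.slice_window[0],
            "window_last": self.slice_window[1],
            "voxel_volume_mm3": self.voxel_volume_mm3,
        }


def compute_volumes(
    result: SegmentationResult,
    geometry: ImageStack,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> VolumeReport:
    """Voxel-count volumes of SAT and VAT over an inclusive 1-based window."""
    first, last = window
    nz = geometry.n_slices
    if not (1 <= first <= last <= nz):
        raise DomainError(
            f"slice window ({first}, {last}) outside stack of {nz} slices"
        )
    voxvol = geometry.voxel_volume_mm3
    rows = []
    for z in range(first - 1, last):
        s = int(result.sat.labels[z].sum())
        v = int(result.vat.labels[z].sum())
        rows.append(
            {
                "slice": z + 1,
                "sat_voxels": s,
                "vat_voxels": v,
                "sat_cm3": s * voxvol / 1000.0,
                "vat_cm3": v * voxvol / 1000.0,
            }
        )
    breakdown = pd.DataFrame(rows)
    sat_cm3 = float(breakdown["sat_cm3"].sum())
    vat_cm3 = float(breakdown["vat_cm3"].sum())
    ratio = vat_cm3 / sat_cm3 if sat_cm3 > 0 else None
    return VolumeReport(
        sat_cm3=sat_cm3,
        vat_cm3=vat_cm3,
        vat_sat_ratio=ratio,
        slice_window=(first, last),
        voxel_volume_mm3=voxvol,
        per_slice_breakdown=breakdown,
    )
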