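"""Readers and writers for the standard formats the pipeline touches.

NIfTI is the canonical intermediate (image + one label volume per
compartment); DICOM series are supported read-only for input plus a minimal
secondary-capture writer used to serialize phantoms.  Physical geometry
(pixel spacing, slice thickness) always comes from headers — a missing
thickness is an error, never a silent default.

In-memory convention: voxel arrays are (n_slices, rows, cols), slice 0 most
caudal.  On disk NIfTI stores (rows, cols, slices) with zooms
(row_spacing, col_spacing, slice_thickness).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import EditError, FormatError
from .segmentation import EditOp, EditScript, SegmentationResult
from .types import ImageStack, MaskStack

__all__ = [
    "read_image",
    "read_nifti",
    "read_dicom_series",
    "write_nifti",
    "write_mask_nifti",
    "write_dicom_series",
    "write_masks",
    "read_mask_nifti",
    "write_cohort",
    "read_cohort",
    "read_edit_script",
    "write_edit_script",
]


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _to_disk_order(voxels: np.ndarray) -> np.ndarray:
    return np.moveaxis(voxels, 0, 2)


def _from_disk_order(data: np.ndarray) -> np.ndarray:
    return np.moveaxis(data, 2, 0)


def write_nifti(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    rs, cs = stack.pixel_spacing_mm
    affine = np.diag([rs, cs, stack.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(_to_disk_order(stack.voxels).astype(np.float64), affine)
    img.header.set_zooms((rs, cs, stack.slice_thickness_mm))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> ImageStack:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI volume ({exc})") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing in NIfTI header")
    return ImageStack(
        voxels=_from_disk_order(data),
        pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=float(zooms[2]),
    )


def write_mask_nifti(mask: MaskStack, geometry: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    rs, cs = geometry.pixel_spacing_mm
    affine = np.diag([rs, cs, geometry.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(_to_disk_order(mask.labels).astype(np.uint8), affine)
    img.header.set_zooms((rs, cs, geometry.slice_thickness_mm))
    nib.save(img, str(path))
    return path


def read_mask_nifti(path: str | Path) -> MaskStack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D label volume")
    return MaskStack(_from_disk_order(data) > 0)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def write_dicom_series(stack: ImageStack, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write one single-frame secondary-capture file per slice.

    Intensities are linearly scaled to uint16 with RescaleSlope/Intercept so
    the stored values round-trip to within quantization.  UIDs are derived
    deterministically from the seed so identical runs produce identical
    series.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rs, cs = stack.pixel_spacing_mm
    lo = float(stack.voxels.min())
    hi = float(stack.voxels.max())
    span = hi - lo if hi > lo else 1.0
    slope = span / 65535.0
    study_uid = generate_uid(entropy_srcs=[f"adiposeg-study-{seed}"])
    series_uid = generate_uid(entropy_srcs=[f"adiposeg-series-{seed}"])
    paths = []
    for z in range(stack.n_slices):
        sl = stack.voxels[z]
        pixels = np.round((sl - lo) / slope).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"adiposeg-instance-{seed}-{z}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.PatientName = "PHANTOM"
        ds.PatientID = f"phantom-{seed}"
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(z) * stack.slice_thickness_mm]
        ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        ds.PixelSpacing = [rs, cs]
        ds.SliceThickness = stack.slice_thickness_mm
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = lo
        ds.PixelData = pixels.tobytes()
        path = out_dir / f"slice_{z + 1:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory: str | Path) -> ImageStack:
    """Read a single-frame-per-slice series, sorting by spatial position.

    Slices are ordered caudal -> cranial by the projection of
    ImagePositionPatient onto the slice normal (cross product of the row and
    column direction cosines) — file names are never trusted for order.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append((p, pydicom.dcmread(str(p))))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"{directory}: no readable DICOM files")

    orientations = []
    for p, ds in datasets:
        if "ImageOrientationPatient" not in ds:
            raise FormatError(f"{p}: missing ImageOrientationPatient")
        orientations.append(np.asarray(ds.ImageOrientationPatient, dtype=float))
    ref = orientations[0]
    for p_ds, ori in zip(datasets, orientations):
        if not np.allclose(ori, ref, atol=1e-4):
            raise FormatError(f"{p_ds[0]}: mixed image orientations in series")

    row_dir, col_dir = ref[:3], ref[3:]
    normal = np.cross(row_dir, col_dir)

    keyed = []
    for p, ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise FormatError(f"{p}: missing ImagePositionPatient")
        if "PixelSpacing" not in ds:
            raise FormatError(f"{p}: missing PixelSpacing metadata")
        if "SliceThickness" not in ds or ds.SliceThickness in (None, ""):
            raise FormatError(f"{p}: missing SliceThickness metadata")
        pos = float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))
        keyed.append((pos, p, ds))
    keyed.sort(key=lambda t: t[0])

    first = keyed[0][2]
    spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    thickness = float(first.SliceThickness)
    slices = []
    for _, p, ds in keyed:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)
    voxels = np.clip(voxels, 0.0, None)  # magnitude images are non-negative
    return ImageStack(
        voxels=voxels, pixel_spacing_mm=spacing, slice_thickness_mm=thickness
    )


def read_image(path: str | Path) -> ImageStack:
    """Dispatch: a directory is a DICOM series, a file is a NIfTI volume."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


# ---------------------------------------------------------------------------
# segmentation results + provenance
# ---------------------------------------------------------------------------

def write_masks(
    result: SegmentationResult,
    geometry: ImageStack,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """One NIfTI label volume per compartment plus a provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, mask in (
        ("sat", result.sat),
        ("vat", result.vat),
        ("nonvat", result.nonvat),
        ("torso", result.torso),
    ):
        paths[name] = write_mask_nifti(mask, geometry, out_dir / f"{name}.nii")
    from . import __version__

    provenance = {
        "software": "adiposeg",
        "version": __version__,
        "seed": seed,
        "params": {k: v for k, v in vars(result.params).items()},
        "edits_applied": result.edits_applied.to_list(),
        "log": result.log,
    }
    sidecar = out_dir / "provenance.json"
    sidecar.write_text(json.dumps(provenance, indent=2, default=str))
    paths["provenance"] = sidecar
    return paths


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False, na_rep="")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# edit scripts
# ---------------------------------------------------------------------------

def read_edit_script(path: str | Path) -> EditScript:
    """Load an edit script from YAML: a list of {slice, compartment, action,
    polygon | mask_file} records; mask files are NIfTI label volumes whose
    slice at the edit's index supplies the region."""
    import yaml

    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return EditScript()
    if not isinstance(raw, list):
        raise EditError(f"{path}: edit script must be a list of edit records")
    ops = []
    for i, rec in enumerate(raw):
        try:
            slice_index = int(rec["slice"])
            compartment = str(rec["compartment"]).upper()
            action = str(rec["action"]).lower()
        except (KeyError, TypeError) as exc:
            raise EditError(f"edit {i}: missing required field ({exc})") from None
        polygon = rec.get("polygon")
        mask = None
        if rec.get("mask_file"):
            mask_path = Path(rec["mask_file"])
            if not mask_path.is_absolute():
                mask_path = path.parent / mask_path
            stack = read_mask_nifti(mask_path)
            if not (1 <= slice_index <= stack.n_slices):
                raise EditError(f"edit {i}: slice {slice_index} outside mask file")
            mask = stack.labels[slice_index - 1]
        ops.append(
            EditOp(
                slice_index=slice_index,
                compartment=compartment,  # type: ignore[arg-type]
                action=action,  # type: ignore[arg-type]
                polygon=[tuple(map(float, p)) for p in polygon] if polygon else None,
                mask=mask,
            )
        )
    return EditScript(ops)


def write_edit_script(script: EditScript, path: str | Path) -> Path:
    import yaml

    recs = []
    for op in script.ops:
        if op.polygon is None:
            raise EditError("write_edit_script: only polygon edits are serializable")
        recs.append(
            {
                "slice": op.slice_index,
                "compartment": op.compartment,
                "action": op.action,
                "polygon": [list(map(float, p)) for p in op.polygon],
            }
        )
    path = Path(path)
    path.write_text(yaml.safe_dump(recs, sort_keys=False))
    return path
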