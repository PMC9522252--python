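"""CT volume container and series I/O.

Geometric conventions used throughout the package:

* slice index 0 is the most SUPERIOR slice (toward the head); per-slice
  physical z positions strictly decrease with slice index, matching a
  head-first supine acquisition read top-down;
* all slices share one in-plane shape;
* voxel values are CT numbers in Hounsfield units with the DICOM rescale
  slope/intercept already applied at read time.

Axial chest CT series are read from directories of single-frame DICOM
instances (the canonical dialect); NIfTI-1 volumes can be read as a
convenience.  Gold-standard overscan tags travel as a flat CSV table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CTVolume",
    "GoldRecord",
    "read_ct_series",
    "write_ct_series",
    "read_nifti",
    "read_gold_table",
    "write_gold_table",
]

#: tolerated relative deviation of inter-slice spacing from its median
SPACING_TOLERANCE = 0.10

_SEX_CODES = {"M", "F"}
_SOURCE_CODES = {"internal", "external"}


@dataclass
class CTVolume:
    """An axial CT volume in HU with the geometry the decision rules need.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, rows, cols)
        CT numbers in HU, slice 0 most superior.
    slice_thickness : float
        Nominal reconstructed slice thickness, mm.
    pixel_spacing : tuple of float
        (row, col) spacing, mm.
    z_positions : ndarray, shape (n_slices,)
        Physical slice positions in mm, strictly decreasing (head -> feet).
    ctdi_vol : float or None
        Volume CT dose index in mGy when the scanner reported it.
    series_id : str
        Opaque series identifier.
    """

    voxels: np.ndarray
    slice_thickness: float
    pixel_spacing: tuple[float, float]
    z_positions: np.ndarray
    ctdi_vol: Optional[float] = None
    series_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D [slice, row, col] array")
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.z_positions.shape != (self.voxels.shape[0],):
            raise ValueError("z_positions must have one entry per slice")
        if self.voxels.shape[0] >= 2 and not np.all(np.diff(self.z_positions) < 0):
            raise ValueError(
                "z_positions must strictly decrease with slice index "
                "(slice 0 most superior)"
            )
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing entries must be > 0")
        if self.ctdi_vol is not None and self.ctdi_vol < 0:
            raise ValueError("ctdi_vol must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_spacing(self) -> float:
        """Physical inter-slice spacing in mm.

        Length computations use this rather than the nominal thickness when
        the two differ, so reported lengths reflect physical coverage.
        """
        if self.n_slices < 2:
            return float(self.slice_thickness)
        return float(np.median(-np.diff(self.z_positions)))

    def copy(self) -> "CTVolume":
        return replace(
            self, voxels=self.voxels.copy(), z_positions=self.z_positions.copy()
        )


@dataclass(frozen=True)
class GoldRecord:
    """One radiologist gold-standard overscan tag with optional covariates."""

    series_id: str
    overscan: bool
    side: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    source: Optional[str] = None
    vendor: Optional[str] = None
    slice_thickness: Optional[float] = None


# ---------------------------------------------------------------------------
# DICOM series I/O
# ---------------------------------------------------------------------------

def _slice_z(ds: pydicom.Dataset) -> float:
    if "ImagePositionPatient" in ds:
        return float(ds.ImagePositionPatient[2])
    if "SliceLocation" in ds:
        return float(ds.SliceLocation)
    raise ValueError(f"instance {ds.get('SOPInstanceUID', '?')} has no z position")


def read_ct_series(path) -> CTVolume:
    """Read a directory of single-frame axial CT DICOM files as one volume.

    Slices are sorted superior-first by physical z regardless of file names,
    the HU rescale is applied, and CTDIvol is taken from dose metadata when
    present.  Mixed series, missing rescale metadata, and non-uniform slice
    spacing (beyond 10% of the median gap) are rejected.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".csv")
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # non-DICOM clutter is ignored
        datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"{path}: need >= 2 DICOM instances of one series")

    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) != 1:
        raise ValueError(f"{path}: mixed series {sorted(series_uids)}")

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(
                f"{path}: instance {ds.SOPInstanceUID} missing rescale metadata"
            )

    datasets.sort(key=_slice_z, reverse=True)  # superior (largest z) first
    z = np.array([_slice_z(ds) for ds in datasets])
    gaps = -np.diff(z)
    if np.any(gaps <= 0):
        raise ValueError(f"{path}: duplicate or non-monotone slice positions")
    med = float(np.median(gaps))
    if np.any(np.abs(gaps - med) > SPACING_TOLERANCE * med):
        raise ValueError(
            f"{path}: non-uniform slice spacing (median {med:.3f} mm, "
            f"range {gaps.min():.3f}-{gaps.max():.3f} mm)"
        )

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"{path}: slices disagree on in-plane shape")

    hu = np.stack(
        [
            ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
            for ds in datasets
        ]
    )
    hu = np.rint(hu).astype(np.int16)

    ds0 = datasets[0]
    ctdi = None
    if "CTDIvol" in ds0 and ds0.CTDIvol not in (None, ""):
        ctdi = float(ds0.CTDIvol)
    spacing = tuple(float(v) for v in ds0.PixelSpacing)
    return CTVolume(
        voxels=hu,
        slice_thickness=float(ds0.SliceThickness),
        pixel_spacing=(spacing[0], spacing[1]),
        z_positions=z,
        ctdi_vol=ctdi,
        series_id=str(ds0.get("SeriesDescription", "") or ds0.SeriesInstanceUID),
    )


def write_ct_series(volume: CTVolume, path) -> list[Path]:
    """Write one DICOM file per slice; inverse of :func:`read_ct_series`.

    Integer HU round-trip bit-exactly; z positions round-trip to 1e-3 mm.
    """
    if volume.n_slices == 0:
        raise ValueError("cannot write an empty volume")
    hu = np.asarray(volume.voxels)
    if not np.all(np.isfinite(hu)):
        raise ValueError("voxels contain non-finite values")
    intercept = -1024.0
    raw = np.rint(hu - intercept)
    if raw.min() < 0 or raw.max() > 65535:
        raise ValueError("HU values outside representable range [-1024, 64511]")

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    name = volume.series_id or "series"
    # arbitrary series ids become deterministic UIDs; the original id is
    # preserved in SeriesDescription and restored on read
    series_uid = generate_uid(entropy_srcs=[name])
    study_uid = generate_uid(entropy_srcs=[str(series_uid), "study"])
    frame_uid = generate_uid(entropy_srcs=[str(series_uid), "frame"])
    written: list[Path] = []
    for i in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        sop_uid = generate_uid(entropy_srcs=[str(series_uid), str(i)])
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = name[:64]
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.PatientName = "PHANTOM"
        ds.PatientID = str(series_uid)[-16:]

        z = float(volume.z_positions[i])
        ds.ImagePositionPatient = [0.0, 0.0, round(z, 4)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = round(z, 4)
        ds.SliceThickness = volume.slice_thickness
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.RescaleType = "HU"
        if volume.ctdi_vol is not None:
            ds.CTDIvol = volume.ctdi_vol

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = hu.shape[1], hu.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = raw[i].astype(np.uint16).tobytes()

        out = path / f"slice_{i:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


def read_nifti(path, slice_thickness: Optional[float] = None) -> CTVolume:
    """Read a NIfTI-1 volume (read-only convenience; DICOM is canonical).

    The last axis is taken as z with the most superior slice first after
    reordering by the affine's z coordinates.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("expected a 3-D NIfTI volume")
    n = data.shape[2]
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    z = np.array([affine[2, 2] * k + affine[2, 3] for k in range(n)])
    order = np.argsort(-z)
    vox = np.transpose(data, (2, 0, 1))[order].astype(np.int16)
    return CTVolume(
        voxels=vox,
        slice_thickness=float(slice_thickness or zooms[2]),
        pixel_spacing=(float(zooms[0]), float(zooms[1])),
        z_positions=z[order],
        series_id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# gold-standard tag table
# ---------------------------------------------------------------------------

def read_gold_table(path) -> list[GoldRecord]:
    """Read radiologist overscan tags from CSV (one record per series_id).

    Required columns: ``series_id``, ``overscan`` (0/1).  Optional:
    ``side``, ``age``, ``sex`` (M/F), ``source`` (internal/external),
    ``vendor``, ``slice_thickness``.
    """
    df = pd.read_csv(path, dtype={"series_id": str})
    if df.empty and "series_id" not in df.columns:
        raise ValueError(f"{path}: missing header with series_id column")
    for col in ("series_id", "overscan"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column '{col}' missing")
    if df["series_id"].duplicated().any():
        dup = df.loc[df["series_id"].duplicated(), "series_id"].iloc[0]
        raise ValueError(f"{path}: duplicated series_id '{dup}'")

    records: list[GoldRecord] = []
    for _, row in df.iterrows():
        sex = _opt_str(row.get("sex"))
        if sex is not None and sex not in _SEX_CODES:
            raise ValueError(f"{path}: unknown sex code '{sex}' (expected M/F)")
        source = _opt_str(row.get("source"))
        if source is not None and source not in _SOURCE_CODES:
            raise ValueError(
                f"{path}: unknown source code '{source}' (expected internal/external)"
            )
        records.append(
            GoldRecord(
                series_id=str(row["series_id"]),
                overscan=bool(int(row["overscan"])),
                side=_opt_str(row.get("side")),
                age=_opt_float(row.get("age")),
                sex=sex,
                source=source,
                vendor=_opt_str(row.get("vendor")),
                slice_thickness=_opt_float(row.get("slice_thickness")),
            )
        )
    return records


def write_gold_table(records: Sequence[GoldRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "series_id": r.series_id,
                "overscan": int(r.overscan),
                "side": r.side or "",
                "age": r.age if r.age is not None else "",
                "sex": r.sex or "",
                "source": r.source or "",
                "vendor": r.vendor or "",
                "slice_thickness": r.slice_thickness
                if r.slice_thickness is not None
                else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "series_id",
            "overscan",
            "side",
            "age",
            "sex",
            "source",
            "vendor",
            "slice_thickness",
        ],
    ).to_csv(path, index=False)


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return str(v)


def _opt_float(v) -> Optional[float]:
    if v is None or v == "":
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f
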