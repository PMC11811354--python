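"""Read and write single-frame CT DICOM objects and assemble series stacks.

All pixel data is carried in Hounsfield units after assembly: the affine
rescale ``HU = stored * slope + intercept`` is applied once when a series is
stacked, so every downstream stage (routing, attenuation statistics, overlay
rendering) sees calibrated attenuation values.

Geometry follows the DICOM patient coordinate system: voxel index order is
(slice, row, col); the slice normal is the cross product of the row and
column direction cosines, and slices are ordered by their position projected
onto that normal.  Inter-slice spacing is derived from consecutive positions;
the SliceThickness tag is retained separately because routing inspects the
tag while geometry trusts the positions.

Only uncompressed little-endian single-frame CT instances are supported;
enhanced multi-frame objects are rejected.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    SecondaryCaptureImageStorage,
    generate_uid,
)

__all__ = [
    "InstanceMeta",
    "SeriesStack",
    "DicomReadError",
    "IneligibleInstanceError",
    "SeriesAssemblyError",
    "read_instance",
    "assemble_series",
    "write_secondary_capture",
]

# Root for UIDs minted by this package (pydicom's public root, namespaced).
UID_PREFIX = "1.2.826.0.1.3680043.8.498."

ORTHO_TOL = 1e-3  # orientation cosines must be unit and orthogonal to this


class DicomReadError(ValueError):
    """File could not be parsed as a DICOM Part-10 object."""


class IneligibleInstanceError(ValueError):
    """Instance parses but lacks tags required for geometric assembly."""


class SeriesAssemblyError(ValueError):
    """Instances cannot be assembled into a consistent series stack."""


@dataclass(frozen=True)
class InstanceMeta:
    """Per-instance metadata needed for routing and stack assembly.

    Optional tags that are absent in the file are ``None`` (never silently
    defaulted): ``procedure_code`` and ``contrast_agent``.
    """

    study_uid: str
    series_uid: str
    sop_uid: str
    instance_number: int
    image_position: tuple[float, float, float]
    image_orientation: tuple[float, float, float, float, float, float]
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    rescale_slope: float
    rescale_intercept: float
    rows: int
    cols: int
    modality: str
    procedure_code: str | None
    contrast_agent: str | None
    received_at: _dt.datetime

    def __post_init__(self) -> None:
        r = np.asarray(self.image_orientation[:3], dtype=float)
        c = np.asarray(self.image_orientation[3:], dtype=float)
        if (
            abs(np.linalg.norm(r) - 1.0) > ORTHO_TOL
            or abs(np.linalg.norm(c) - 1.0) > ORTHO_TOL
            or abs(float(np.dot(r, c))) > ORTHO_TOL
        ):
            raise IneligibleInstanceError(
                "image orientation cosines are not two orthogonal unit vectors"
            )
        if min(self.pixel_spacing) <= 0:
            raise IneligibleInstanceError("pixel spacing must be positive")
        if self.slice_thickness <= 0:
            raise IneligibleInstanceError("slice thickness must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Slice normal: cross product of the row and column cosines."""
        r = np.asarray(self.image_orientation[:3], dtype=float)
        c = np.asarray(self.image_orientation[3:], dtype=float)
        return np.cross(r, c)


@dataclass
class SeriesStack:
    """A geometrically consistent 3-D HU volume assembled from one series.

    ``voxels`` has shape (n_slices, rows, cols); ``meta`` is sorted along the
    slice normal in the same order as the voxel planes.  ``spacing`` is
    (inter-slice, row, col) in mm, with the inter-slice component derived
    from consecutive slice positions.
    """

    meta: list[InstanceMeta]
    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_thickness_set: frozenset[float] = field(default_factory=frozenset)

    @property
    def study_uid(self) -> str:
        return self.meta[0].study_uid

    @property
    def series_uid(self) -> str:
        return self.meta[0].series_uid

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def normal(self) -> np.ndarray:
        return self.meta[0].normal

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _required(ds: Dataset, keyword: str):
    value = ds.get(keyword)
    if value is None:
        raise IneligibleInstanceError(f"missing required tag {keyword}")
    return value


def read_instance(path: str | Path) -> tuple[InstanceMeta, np.ndarray]:
    """Read one single-frame CT/SC instance.

    Returns the metadata plus the *stored-value* pixel plane (the rescale is
    applied later, at assembly).  Raises :class:`DicomReadError` for files
    that are not DICOM and :class:`IneligibleInstanceError` for DICOM files
    missing the geometry tags needed downstream.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several unrelated types
        raise DicomReadError(f"not a parsable DICOM file: {path}") from exc

    if int(ds.get("NumberOfFrames", 1)) != 1:
        raise IneligibleInstanceError(
            f"enhanced multi-frame objects are not supported: {path}"
        )

    procedure_code = None
    seq = ds.get("ProcedureCodeSequence")
    if seq:
        procedure_code = str(seq[0].get("CodeValue", "")) or None

    contrast = ds.get("ContrastBolusAgent")
    contrast_agent = str(contrast) if contrast not in (None, "") else None

    received_at = _dt.datetime.fromtimestamp(
        path.stat().st_mtime, tz=_dt.timezone.utc
    )

    meta = InstanceMeta(
        study_uid=str(_required(ds, "StudyInstanceUID")),
        series_uid=str(_required(ds, "SeriesInstanceUID")),
        sop_uid=str(_required(ds, "SOPInstanceUID")),
        instance_number=int(ds.get("InstanceNumber", 0)),
        image_position=tuple(float(v) for v in _required(ds, "ImagePositionPatient")),
        image_orientation=tuple(
            float(v) for v in _required(ds, "ImageOrientationPatient")
        ),
        pixel_spacing=tuple(float(v) for v in _required(ds, "PixelSpacing")),
        slice_thickness=float(_required(ds, "SliceThickness")),
        rescale_slope=float(ds.get("RescaleSlope", 1.0)),
        rescale_intercept=float(ds.get("RescaleIntercept", 0.0)),
        rows=int(_required(ds, "Rows")),
        cols=int(_required(ds, "Columns")),
        modality=str(ds.get("Modality", "")),
        procedure_code=procedure_code,
        contrast_agent=contrast_agent,
        received_at=received_at,
    )
    plane = ds.pixel_array
    if plane.shape[:2] != (meta.rows, meta.cols):
        raise IneligibleInstanceError(f"pixel data shape mismatch in {path}")
    return meta, plane


def read_study(study_dir: str | Path) -> list[tuple[InstanceMeta, np.ndarray]]:
    """Read every ``*.dcm`` instance under one study directory."""
    study_dir = Path(study_dir)
    out = []
    for p in sorted(study_dir.glob("*.dcm")):
        out.append(read_instance(p))
    return out


def assemble_series(
    instances: Sequence[tuple[InstanceMeta, np.ndarray]],
) -> SeriesStack:
    """Assemble instances of one series into a sorted HU stack.

    Ordering of the input is irrelevant: slices are sorted by position
    projected on the slice normal.  Duplicate projected positions and mixed
    in-plane geometry are errors.
    """
    if len(instances) < 2:
        raise SeriesAssemblyError("a series stack needs at least 2 slices")
    metas = [m for m, _ in instances]
    series_uids = {m.series_uid for m in metas}
    if len(series_uids) != 1:
        raise SeriesAssemblyError(f"mixed series UIDs: {sorted(series_uids)}")
    if len({(m.rows, m.cols) for m in metas}) != 1:
        raise SeriesAssemblyError("mixed Rows/Columns within series")
    if len({m.pixel_spacing for m in metas}) != 1:
        raise SeriesAssemblyError("mixed PixelSpacing within series")
    if len({m.image_orientation for m in metas}) != 1:
        raise SeriesAssemblyError("mixed ImageOrientationPatient within series")

    normal = metas[0].normal
    projections = [float(np.dot(m.image_position, normal)) for m in metas]
    order = sorted(range(len(metas)), key=lambda i: projections[i])
    sorted_proj = [projections[i] for i in order]
    steps = np.diff(sorted_proj)
    if np.any(np.abs(steps) < 1e-6):
        raise SeriesAssemblyError("duplicate slice positions along the normal")

    inter_slice = float(np.median(steps))
    planes = []
    metas_sorted = []
    for i in order:
        m, plane = instances[i]
        hu = plane.astype(np.float64) * m.rescale_slope + m.rescale_intercept
        planes.append(hu)
        metas_sorted.append(m)
    voxels = np.stack(planes, axis=0)

    row_mm, col_mm = metas[0].pixel_spacing
    return SeriesStack(
        meta=metas_sorted,
        voxels=voxels,
        spacing=(inter_slice, row_mm, col_mm),
        slice_thickness_set=frozenset(m.slice_thickness for m in metas),
    )


def _file_meta(sop_class_uid: str, sop_uid: str) -> FileMetaDataset:
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = sop_class_uid
    fm.MediaStorageSOPInstanceUID = sop_uid
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    return fm


def write_ct_instance(
    out_path: Path,
    *,
    study_uid: str,
    series_uid: str,
    sop_uid: str,
    instance_number: int,
    stored_plane: np.ndarray,
    image_position: Sequence[float],
    image_orientation: Sequence[float],
    pixel_spacing: Sequence[float],
    slice_thickness: float,
    rescale_slope: float = 1.0,
    rescale_intercept: float = -1024.0,
    procedure_code: str | None = None,
    contrast_agent: str | None = None,
    series_description: str = "",
) -> None:
    """Write one uncompressed single-frame CT instance (16-bit unsigned)."""
    if stored_plane.dtype != np.uint16:
        raise ValueError("stored_plane must be uint16")
    ds = Dataset()
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.SeriesDescription = series_description
    ds.InstanceNumber = instance_number
    ds.ImagePositionPatient = [float(v) for v in image_position]
    ds.ImageOrientationPatient = [float(v) for v in image_orientation]
    ds.PixelSpacing = [float(v) for v in pixel_spacing]
    ds.SliceThickness = float(slice_thickness)
    ds.RescaleSlope = rescale_slope
    ds.RescaleIntercept = rescale_intercept
    ds.Rows, ds.Columns = stored_plane.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = stored_plane.tobytes()
    if procedure_code is not None:
        item = Dataset()
        item.CodeValue = procedure_code
        item.CodingSchemeDesignator = "C4"  # CPT
        item.CodeMeaning = "procedure"
        ds.ProcedureCodeSequence = [item]
    if contrast_agent is not None:
        ds.ContrastBolusAgent = contrast_agent
    ds.file_meta = _file_meta(CTImageStorage, sop_uid)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(out_path, enforce_file_format=True)


def write_secondary_capture(
    stack: SeriesStack,
    rgb_planes: Sequence[np.ndarray],
    source_refs: Sequence[InstanceMeta],
    out_dir: str | Path,
    *,
    series_description: str = "AI QC overlay",
    series_uid: str | None = None,
) -> list[Path]:
    """Write an RGB Secondary Capture series derived from ``stack``.

    The SC series gets a fresh series UID under the *same* study UID as the
    source, so PACS-style study grouping holds, and each instance carries a
    SourceImageSequence referencing the source SOP instance it was derived
    from.  Returns the written file paths in slice order.
    """
    if len(source_refs) == 0:
        raise ValueError("source_refs must not be empty")
    if len(rgb_planes) != len(source_refs):
        raise ValueError(
            f"plane count {len(rgb_planes)} != source instance count {len(source_refs)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study_uid = source_refs[0].study_uid
    if series_uid is None:
        series_uid = generate_uid(prefix=UID_PREFIX)
    paths: list[Path] = []
    for i, (plane, src) in enumerate(zip(rgb_planes, source_refs)):
        if plane.dtype != np.uint8 or plane.ndim != 3 or plane.shape[2] != 3:
            raise ValueError("rgb planes must be uint8 arrays of shape (r, c, 3)")
        sop_uid = generate_uid(prefix=UID_PREFIX)
        ds = Dataset()
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.ConversionType = "WSD"
        ds.SeriesDescription = series_description
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [float(v) for v in src.image_position]
        ds.ImageOrientationPatient = [float(v) for v in src.image_orientation]
        ds.PixelSpacing = [float(v) for v in src.pixel_spacing]
        ds.SliceThickness = float(src.slice_thickness)
        ds.Rows, ds.Columns = plane.shape[:2]
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(plane).tobytes()
        ref = Dataset()
        ref.ReferencedSOPClassUID = CTImageStorage
        ref.ReferencedSOPInstanceUID = src.sop_uid
        ds.SourceImageSequence = [ref]
        ds.DerivationDescription = "AI organ segmentation QC overlay"
        ds.file_meta = _file_meta(SecondaryCaptureImageStorage, sop_uid)
        path = out_dir / f"{sop_uid}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def new_uid(entropy: Sequence[str] | None = None) -> str:
    """Mint a UID; with ``entropy`` the UID is deterministic in its inputs."""
    if entropy is None:
        return generate_uid(prefix=UID_PREFIX)
    return generate_uid(prefix=UID_PREFIX, entropy_srcs=[str(e) for e in entropy])
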