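"""Reading DICOM series into oriented volumes, and NIfTI round-tripping.

All geometry lives in the DICOM patient coordinate system (LPS).  A volume's
``data`` array is indexed ``[i, j, k]`` where ``i`` runs along the image rows
(increasing column index), ``j`` along the columns (increasing row index) and
``k`` across slices; ``direction`` holds the unit direction of each index axis
in its columns, so a voxel centre sits at ``origin + direction @ (spacing *
index)``.  NIfTI export converts to RAS by negating the first two axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

__all__ = [
    "HeaderRecord",
    "ImageVolume",
    "LabelVolume",
    "SeriesRead",
    "DicomReadError",
    "read_series",
    "voxel_volume",
    "save_nifti",
    "load_nifti",
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
    "TISSUE_CLASSES",
]

# Tissue label conventions used throughout the package.
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_CLASSES = (CSF, GM, WM)

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


class DicomReadError(RuntimeError):
    """Raised when a directory yields no readable DICOM series."""


@dataclass
class HeaderRecord:
    """Acquisition and identity metadata of one DICOM series.

    Times are milliseconds, spacings millimetres, flip angle degrees,
    field strength tesla.  ``inversion_time == 0`` means "absent".
    """

    scanning_sequence: str = "unknown"  # SE, GR, IR, EP or unknown
    repetition_time: float = 0.0
    echo_time: float | None = None
    inversion_time: float = 0.0
    flip_angle: float = 0.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0
    spacing_between_slices: float | None = None
    matrix: tuple[int, int] = (1, 1)
    n_slices: int = 1
    field_strength: float = 1.5
    manufacturer: str = ""
    model: str = ""
    contrast_agent: str = ""
    series_number: int = 1
    series_description: str = ""
    diffusion_bvalue: float | None = None
    n_temporal_positions: int = 1
    identity: dict[str, str] = field(default_factory=dict)
    private_tags: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.repetition_time < 0 or (self.echo_time or 0) < 0:
            raise ValueError("repetition/echo time must be non-negative")
        if min(self.matrix) < 1 or self.n_slices < 1:
            raise ValueError("matrix and n_slices must be >= 1")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be positive")

    def copy(self) -> "HeaderRecord":
        return replace(
            self,
            identity=dict(self.identity),
            private_tags=list(self.private_tags),
        )


@dataclass
class ImageVolume:
    """A 3D scalar image with LPS geometry (spacing/origin in mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-6:
            raise ValueError("direction must be orthonormal (|det| = 1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        """4x4 index -> LPS affine (voxel centres)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (three arrays, one per axis) of every voxel."""
        idx = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        aff = self.affine()
        coords = [
            aff[d, 0] * idx[0] + aff[d, 1] * idx[1] + aff[d, 2] * idx[2] + aff[d, 3]
            for d in range(3)
        ]
        return coords[0], coords[1], coords[2]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.spacing, self.origin, self.direction.copy())

    def same_grid(self, other: "ImageVolume | LabelVolume", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class LabelVolume(ImageVolume):
    """Integer tissue labels over {background, CSF, GM, WM} on a grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int16, copy=False)
        bad = np.setdiff1d(np.unique(self.data), [BACKGROUND, CSF, GM, WM])
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2,3}}: {bad.tolist()}")


@dataclass
class SeriesRead:
    """One series from a directory: a volume, its header and any problems."""

    volume: ImageVolume | None
    header: HeaderRecord
    problems: list[str] = field(default_factory=list)

    @property
    def readable(self) -> bool:
        return self.volume is not None and not self.problems


def voxel_volume(obj: HeaderRecord | ImageVolume) -> float:
    """Voxel volume in mm^3 (product of the three spacings)."""
    if isinstance(obj, ImageVolume):
        return obj.voxel_volume
    if isinstance(obj, HeaderRecord):
        dz = obj.spacing_between_slices or obj.slice_thickness
        if dz is None or dz <= 0:
            raise ValueError("slice spacing unknown")
        return float(obj.pixel_spacing[0] * obj.pixel_spacing[1] * dz)
    raise TypeError(f"cannot compute voxel volume of {type(obj)!r}")


# ---------------------------------------------------------------------------
# DICOM reading


def _get(ds: pydicom.Dataset, name: str, default=None):
    value = getattr(ds, name, None)
    if value in (None, ""):
        return default
    return value


def _scanning_sequence(ds: pydicom.Dataset) -> str:
    raw = _get(ds, "ScanningSequence", "")
    values = raw if isinstance(raw, (list, pydicom.multival.MultiValue)) else [raw]
    values = [str(v) for v in values]
    for code in ("EP", "GR", "SE", "IR"):
        if code in values:
            return code
    return "unknown"


_IDENTITY_ATTRS = {
    "patient_name": "PatientName",
    "patient_id": "PatientID",
    "birth_date": "PatientBirthDate",
    "study_date": "StudyDate",
    "accession": "AccessionNumber",
    "institution": "InstitutionName",
    "institution_address": "InstitutionAddress",
    "referring_physician": "ReferringPhysicianName",
    "operators": "OperatorsName",
    "station_name": "StationName",
    "patient_address": "PatientAddress",
    "other_patient_ids": "OtherPatientIDs",
}


def header_from_dataset(ds: pydicom.Dataset) -> HeaderRecord:
    """Extract a typed :class:`HeaderRecord` from one slice dataset."""
    identity = {}
    for key, attr in _IDENTITY_ATTRS.items():
        value = _get(ds, attr)
        if value is not None:
            identity[key] = str(value)
    private = []
    for elem in ds:
        if elem.tag.group % 2 == 1:
            private.append((elem.tag.group, elem.tag.element, str(elem.value)))
    spacing = [float(v) for v in _get(ds, "PixelSpacing", [1.0, 1.0])]
    te = _get(ds, "EchoTime")
    bval = _get(ds, "DiffusionBValue")
    return HeaderRecord(
        scanning_sequence=_scanning_sequence(ds),
        repetition_time=float(_get(ds, "RepetitionTime", 0.0)),
        echo_time=None if te is None else float(te),
        inversion_time=float(_get(ds, "InversionTime", 0.0)),
        flip_angle=float(_get(ds, "FlipAngle", 0.0)),
        pixel_spacing=(spacing[0], spacing[1]),
        slice_thickness=float(_get(ds, "SliceThickness", 1.0)),
        spacing_between_slices=(
            None
            if _get(ds, "SpacingBetweenSlices") is None
            else float(ds.SpacingBetweenSlices)
        ),
        matrix=(int(_get(ds, "Columns", 1)), int(_get(ds, "Rows", 1))),
        n_slices=1,
        field_strength=float(_get(ds, "MagneticFieldStrength", 1.5)),
        manufacturer=str(_get(ds, "Manufacturer", "")),
        model=str(_get(ds, "ManufacturerModelName", "")),
        contrast_agent=str(_get(ds, "ContrastBolusAgent", "")).strip(),
        series_number=int(_get(ds, "SeriesNumber", 1)),
        series_description=str(_get(ds, "SeriesDescription", "")),
        diffusion_bvalue=None if bval is None else float(bval),
        n_temporal_positions=int(_get(ds, "NumberOfTemporalPositions", 1)),
        identity=identity,
        private_tags=private,
    )


def _assemble_series(slices: list[pydicom.Dataset]) -> SeriesRead:
    header = header_from_dataset(slices[0])
    problems: list[str] = []

    iop0 = np.array([float(v) for v in slices[0].ImageOrientationPatient])
    for ds in slices[1:]:
        iop = np.array([float(v) for v in ds.ImageOrientationPatient])
        if not np.allclose(iop, iop0, atol=1e-4):
            problems.append("inconsistent orientation within series")
            break
        if not np.allclose(
            [float(v) for v in ds.PixelSpacing],
            header.pixel_spacing,
            atol=1e-6,
        ):
            problems.append("inconsistent pixel spacing within series")
            break

    row_dir, col_dir = iop0[:3], iop0[3:]
    normal = np.cross(row_dir, col_dir)
    positions = np.array(
        [[float(v) for v in ds.ImagePositionPatient] for ds in slices]
    )
    order = np.argsort(positions @ normal, kind="stable")
    slices = [slices[i] for i in order]
    positions = positions[order]

    if len(slices) > 1:
        gaps = np.diff(positions @ normal)
        dz = float(np.median(gaps))
        if dz <= 0:
            problems.append("duplicate slice positions")
            dz = header.slice_thickness
        elif np.any(np.abs(gaps - dz) > 0.1 * dz):
            problems.append("non-uniform slice spacing")
    else:
        dz = header.spacing_between_slices or header.slice_thickness

    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(_get(ds, "RescaleSlope", 1.0))
        intercept = float(_get(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    # pixel_array is [row, col]; transpose to [i (col), j (row)]
    data = np.stack([a.T for a in arrays], axis=-1)

    direction = np.column_stack([row_dir, col_dir, normal])
    volume = ImageVolume(
        data,
        spacing=(header.pixel_spacing[1], header.pixel_spacing[0], dz),
        origin=tuple(positions[0]),
        direction=direction,
    )
    header.n_slices = len(slices)
    header.spacing_between_slices = dz
    if problems:
        return SeriesRead(None, header, problems)
    return SeriesRead(volume, header)


def read_series(directory: str | Path) -> list[SeriesRead]:
    """Read every DICOM series under ``directory`` (non-recursive).

    Files are grouped by SeriesInstanceUID and slices sorted by the
    projection of ImagePositionPatient onto the slice normal, so the result
    is independent of on-disk file order.  A series with inconsistent
    geometry is returned flagged (``volume is None``) rather than aborting
    the batch.
    """
    directory = Path(directory)
    groups: dict[str, list[pydicom.Dataset]] = {}
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            continue
        groups.setdefault(str(ds.SeriesInstanceUID), []).append(ds)
    if not groups:
        raise DicomReadError(f"no readable DICOM files in {directory}")
    out = []
    for uid in sorted(groups):
        out.append(_assemble_series(groups[uid]))
    return out


# ---------------------------------------------------------------------------
# NIfTI


def save_nifti(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1, converting LPS geometry to RAS."""
    aff = volume.affine()
    ras = np.eye(4)
    ras[:3, :3] = _LPS_TO_RAS @ aff[:3, :3]
    ras[:3, 3] = _LPS_TO_RAS @ aff[:3, 3]
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), ras)
    nib.save(img, str(path))


def load_nifti(path: str | Path, labels: bool = False) -> ImageVolume:
    """Read a NIfTI file written by :func:`save_nifti` back into LPS."""
    img = nib.load(str(path))
    ras = img.affine
    lps = np.eye(4)
    lps[:3, :3] = _LPS_TO_RAS @ ras[:3, :3]
    lps[:3, 3] = _LPS_TO_RAS @ ras[:3, 3]
    scales = np.linalg.norm(lps[:3, :3], axis=0)
    direction = lps[:3, :3] / scales
    data = np.asarray(img.dataobj, dtype=np.float64)
    cls = LabelVolume if labels else ImageVolume
    return cls(
        np.round(data).astype(np.int16) if labels else data,
        spacing=tuple(scales),
        origin=tuple(lps[:3, 3]),
        direction=direction,
    )
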