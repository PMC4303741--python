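"""Synthetic head phantoms with analytic ground truth, written as DICOM.

The phantom is a family of nested ellipsoids — white matter inside grey
matter inside CSF inside skull inside scalp — with a face lobe attached
anteriorly (the -y / anterior direction in LPS).  Because every structure is
an ellipsoid, tissue volumes have closed forms (4/3 pi abc, scaled by the
pose), which is what makes the downstream volumetry testable without any
reference data.  Subject pose (rotation / translation / uniform scale) is
applied analytically to the geometry, so the posed ground truth is exact:
no resampling is involved in generating a phantom.

The header profiles emulate the heterogeneity of routinely acquired clinical
MRI: four vendor/model combinations with their typical T1w/PDw acquisition
parameters, mixed field strengths, occasional contrast agent and vendor
private tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dicom_io import (
    BACKGROUND,
    CSF,
    GM,
    WM,
    HeaderRecord,
    ImageVolume,
    LabelVolume,
)

__all__ = [
    "Ellipsoid",
    "Pose",
    "PhantomSpec",
    "Atlas",
    "AtlasSet",
    "PhantomGeometryError",
    "generate_regions",
    "generate_phantom",
    "generate_atlas_set",
    "write_dicom_series",
    "analytic_volumes_ml",
    "VENDOR_PROFILES",
    "AIR",
    "SCALP",
    "SKULL",
    "R_CSF",
    "R_GM",
    "R_WM",
    "FACE",
]

# Structure codes of the region map (finer than the tissue labels).
AIR, SCALP, SKULL, R_CSF, R_GM, R_WM, FACE = 0, 1, 2, 3, 4, 5, 6

_REGION_TO_LABEL = {
    AIR: BACKGROUND,
    SCALP: BACKGROUND,
    SKULL: BACKGROUND,
    R_CSF: CSF,
    R_GM: GM,
    R_WM: WM,
    FACE: BACKGROUND,
}


class PhantomGeometryError(ValueError):
    """Raised when the requested ellipsoids cannot be nested."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre and semi-axes in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class Pose:
    """Rigid + uniform-scale perturbation of the phantom in patient space."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = (math.radians(a) for a in self.rotation_deg)
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return mz @ my @ mx

    def inverse_map(self, x, y, z):
        """Map posed physical coordinates back to canonical phantom space."""
        rinv = self.rotation_matrix().T
        tx, ty, tz = self.translation_mm
        u, v, w = x - tx, y - ty, z - tz
        q0 = rinv[0, 0] * u + rinv[0, 1] * v + rinv[0, 2] * w
        q1 = rinv[1, 0] * u + rinv[1, 1] * v + rinv[1, 2] * w
        q2 = rinv[2, 0] * u + rinv[2, 1] * v + rinv[2, 2] * w
        s = self.scale
        return q0 / s, q1 / s, q2 / s


DEFAULT_GEOMETRY: dict[str, Ellipsoid] = {
    # Concentric brain shells, shifted slightly posterior of the head centre.
    "head": Ellipsoid((0.0, 5.0, 0.0), (70.0, 80.0, 58.0)),
    "skull": Ellipsoid((0.0, 10.0, 0.0), (64.0, 72.0, 52.0)),
    "csf": Ellipsoid((0.0, 10.0, 0.0), (58.0, 66.0, 46.0)),
    "gm": Ellipsoid((0.0, 10.0, 0.0), (50.0, 58.0, 40.0)),
    "wm": Ellipsoid((0.0, 10.0, 0.0), (38.0, 44.0, 30.0)),
    # Face lobe protruding anteriorly, well clear of the intracranial shells.
    "face": Ellipsoid((0.0, -85.0, -12.0), (28.0, 18.0, 28.0)),
}

DEFAULT_CLASS_MEANS: dict[int, float] = {
    AIR: 0.0,
    SCALP: 300.0,
    SKULL: 100.0,
    R_CSF: 450.0,
    R_GM: 620.0,
    R_WM: 800.0,
    FACE: 300.0,
}

# Noise SD of 8.5 = 5% of the smallest tissue class-mean separation (170
# between CSF and GM), the regime the recovery experiments are run in.
DEFAULT_NOISE_SD = 8.5

# Vendor/model header profiles mirroring the heterogeneity of multi-scanner
# clinical archives (times in ms, field strength in tesla).
VENDOR_PROFILES: list[dict] = [
    dict(manufacturer="GE", model="Discovery", scanning_sequence="GR",
         repetition_time=7.9, echo_time=3.1, inversion_time=450.0,
         flip_angle=12.0, field_strength=3.0),
    dict(manufacturer="GE", model="Signa", scanning_sequence="SE",
         repetition_time=565.0, echo_time=12.0, inversion_time=0.0,
         flip_angle=90.0, field_strength=1.5),
    dict(manufacturer="Siemens", model="Sonata", scanning_sequence="SE",
         repetition_time=2500.0, echo_time=15.0, inversion_time=0.0,
         flip_angle=90.0, field_strength=1.5),
    dict(manufacturer="Philips", model="NT Intera", scanning_sequence="GR",
         repetition_time=16.3, echo_time=7.6, inversion_time=400.0,
         flip_angle=30.0, field_strength=1.5),
]


@dataclass
class PhantomSpec:
    """Full description of one synthetic examination."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tissue_geometry: dict[str, Ellipsoid] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY)
    )
    class_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    class_noise_sd: float = DEFAULT_NOISE_SD
    bias_amplitude: float = 0.0
    pose: Pose = field(default_factory=Pose)
    header_profile: dict = field(default_factory=lambda: dict(VENDOR_PROFILES[0]))
    identity_profile: dict[str, str] = field(
        default_factory=lambda: {
            "patient_name": "PHANTOM^TEST",
            "patient_id": "PH000",
            "birth_date": "19600115",
            "study_date": "20100401",
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if self.class_noise_sd < 0:
            raise ValueError("class_noise_sd must be >= 0")
        for name in ("head", "skull", "csf", "gm", "wm", "face"):
            if name not in self.tissue_geometry:
                raise ValueError(f"tissue_geometry missing {name!r}")

    def origin(self) -> tuple[float, float, float]:
        """Origin placing the grid centre at (0, 0, 0) in patient space."""
        return tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.spacing)
        )

    def grid_coords(self):
        idx = np.meshgrid(
            *(np.arange(n, dtype=float) for n in self.grid_shape), indexing="ij"
        )
        o = self.origin()
        return tuple(o[d] + idx[d] * self.spacing[d] for d in range(3))


def generate_regions(spec: PhantomSpec) -> np.ndarray:
    """Voxelize the posed structure map (codes AIR..FACE) on the grid."""
    x, y, z = spec.grid_coords()
    qx, qy, qz = spec.pose.inverse_map(x, y, z)
    g = spec.tissue_geometry
    regions = np.full(spec.grid_shape, AIR, dtype=np.int16)
    regions[g["head"].contains(qx, qy, qz)] = SCALP
    regions[g["skull"].contains(qx, qy, qz)] = SKULL
    regions[g["csf"].contains(qx, qy, qz)] = R_CSF
    regions[g["gm"].contains(qx, qy, qz)] = R_GM
    regions[g["wm"].contains(qx, qy, qz)] = R_WM
    in_face = g["face"].contains(qx, qy, qz)
    if np.any(in_face & np.isin(regions, [R_CSF, R_GM, R_WM])):
        raise PhantomGeometryError(
            "face ellipsoid intersects the intracranial region; "
            "the structures cannot be nested"
        )
    regions[in_face & (regions <= SKULL)] = FACE
    return regions


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order multiplicative field with max |field - 1| = amplitude."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    x, y, z = spec.grid_coords()
    extent = [(n - 1) / 2.0 * s for n, s in zip(spec.grid_shape, spec.spacing)]
    xn, yn, zn = x / extent[0], y / extent[1], z / extent[2]
    terms = [xn, yn, zn, xn * yn, yn * zn, xn * zn, xn**2, yn**2, zn**2]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    raw = sum(c * t for c, t in zip(coeffs, terms))
    peak = np.max(np.abs(raw))
    if peak == 0:
        return np.ones(spec.grid_shape)
    return 1.0 + spec.bias_amplitude * raw / peak


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, LabelVolume, HeaderRecord]:
    """Render one phantom: intensity volume, tissue labels and DICOM header.

    Intensities are per-voxel class mean plus Gaussian noise, multiplied by
    the bias field and rounded to integers (the 16-bit values a scanner
    would store), clipped at zero.  Identical spec + seed is bit-for-bit
    reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    regions = generate_regions(spec)
    means = np.zeros(max(spec.class_means) + 1)
    for code, mean in spec.class_means.items():
        means[code] = mean
    intensity = means[regions]
    if spec.class_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.class_noise_sd, regions.shape)
    intensity = intensity * _bias_field(spec, rng)
    intensity = np.clip(np.round(intensity), 0, 65535)

    labels = np.vectorize(_REGION_TO_LABEL.get, otypes=[np.int16])(regions)
    origin = spec.origin()
    volume = ImageVolume(intensity, spec.spacing, origin)
    label_volume = LabelVolume(labels, spec.spacing, origin)

    profile = dict(spec.header_profile)
    private = profile.pop("private_tags", [(0x0019, 0x1010, "SYNTH-PAYLOAD")])
    header = HeaderRecord(
        pixel_spacing=(spec.spacing[1], spec.spacing[0]),
        slice_thickness=spec.spacing[2],
        spacing_between_slices=spec.spacing[2],
        matrix=(spec.grid_shape[0], spec.grid_shape[1]),
        n_slices=spec.grid_shape[2],
        identity=dict(spec.identity_profile),
        private_tags=list(private),
        **profile,
    )
    return volume, label_volume, header


def analytic_volumes_ml(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form tissue volumes (ml) of the posed phantom.

    Shell volumes are differences of nested ellipsoid volumes; the uniform
    pose scale multiplies every volume by scale**3.
    """
    g = spec.tissue_geometry
    s3 = spec.pose.scale**3
    wm = g["wm"].volume_mm3
    gm = g["gm"].volume_mm3 - wm
    csf = g["csf"].volume_mm3 - g["gm"].volume_mm3
    icv = g["csf"].volume_mm3
    return {
        "wm_ml": wm * s3 / 1000.0,
        "gm_ml": gm * s3 / 1000.0,
        "csf_ml": csf * s3 / 1000.0,
        "brain_ml": (wm + gm) * s3 / 1000.0,
        "icv_ml": icv * s3 / 1000.0,
    }


# ---------------------------------------------------------------------------
# Atlas sets


@dataclass
class Atlas:
    """One atlas: intensity, expert-style labels and the derived masks."""

    intensity: ImageVolume
    labels: LabelVolume
    intracranial_mask: np.ndarray
    cerebrum_mask: np.ndarray
    face_exclusion_mask: np.ndarray  # 1 = keep, 0 = face

    def __post_init__(self) -> None:
        for mask in (
            self.intracranial_mask,
            self.cerebrum_mask,
            self.face_exclusion_mask,
        ):
            if mask.shape != self.intensity.shape:
                raise ValueError("atlas components must share one grid")


@dataclass
class AtlasSet:
    atlases: list[Atlas]

    @property
    def count(self) -> int:
        return len(self.atlases)

    def __iter__(self):
        return iter(self.atlases)


def _atlas_from_spec(spec: PhantomSpec) -> Atlas:
    from scipy.ndimage import binary_dilation

    volume, labels, _ = generate_phantom(spec)
    regions = generate_regions(spec)
    intracranial = (labels.data > 0).astype(np.uint8)
    cerebrum = np.isin(labels.data, [GM, WM]).astype(np.uint8)
    # Dilate the face region by one voxel so sub-voxel registration error
    # cannot leave a face shell behind after masking.
    face = binary_dilation(regions == FACE)
    face_exclusion = (~face).astype(np.uint8)
    return Atlas(volume, labels, intracranial, cerebrum, face_exclusion)


@dataclass(frozen=True)
class AtlasJitter:
    """Per-atlas perturbation ranges (uniform, symmetric about zero)."""

    rotation_deg: float = 5.0
    translation_mm: float = 5.0
    scale: float = 0.03
    intensity_fraction: float = 0.05

    @classmethod
    def none(cls) -> "AtlasJitter":
        return cls(0.0, 0.0, 0.0, 0.0)


def generate_atlas_set(
    spec: PhantomSpec,
    n: int = 6,
    jitter: AtlasJitter | None = None,
    seed: int = 0,
) -> AtlasSet:
    """Generate ``n`` atlases as pose/intensity-jittered phantoms.

    Jitter perturbs pose and class means only (shape is shared), emulating
    different healthy template subjects scanned on different hardware.
    """
    if n < 1:
        raise ValueError("need at least one atlas")
    jitter = AtlasJitter() if jitter is None else jitter
    rng = np.random.default_rng(seed)
    if jitter == AtlasJitter.none():
        # fully deterministic degenerate case: n copies of the base phantom
        return AtlasSet([_atlas_from_spec(spec)] * n)
    atlases = []
    for i in range(n):
        rot = tuple(rng.uniform(-jitter.rotation_deg, jitter.rotation_deg, 3))
        tr = tuple(rng.uniform(-jitter.translation_mm, jitter.translation_mm, 3))
        sc = 1.0 + rng.uniform(-jitter.scale, jitter.scale)
        means = {
            code: mean * (1.0 + rng.uniform(-jitter.intensity_fraction,
                                            jitter.intensity_fraction))
            for code, mean in spec.class_means.items()
        }
        sub = replace(
            spec,
            pose=Pose(rot, tr, sc),
            class_means=means,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        atlases.append(_atlas_from_spec(sub))
    return AtlasSet(atlases)


# ---------------------------------------------------------------------------
# DICOM writing


def write_dicom_series(
    volume: ImageVolume,
    header: HeaderRecord,
    out_dir: str | Path,
    series_uid_key: str = "series-0",
) -> list[Path]:
    """Write one DICOM file per slice (explicit VR little endian).

    UIDs are generated deterministically from ``series_uid_key`` and the
    slice index, so a given phantom always writes byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = volume.shape
    if header.matrix != (nx, ny) or header.n_slices != nz:
        raise ValueError("header matrix/slice count inconsistent with volume")

    pixels = np.asarray(volume.data)
    if np.any(pixels < 0) or np.any(pixels > 65535):
        raise ValueError("pixel values must fit uint16")
    pixels = pixels.astype(np.uint16)

    series_uid = generate_uid(entropy_srcs=[series_uid_key])
    study_uid = generate_uid(entropy_srcs=[series_uid_key, "study"])
    frame_uid = generate_uid(entropy_srcs=[series_uid_key, "frame"])
    direction = volume.direction
    origin = np.asarray(volume.origin)
    paths = []
    for k in range(nz):
        ds = pydicom.Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
        ds.SOPInstanceUID = generate_uid(entropy_srcs=[series_uid_key, str(k)])
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "MR"
        ds.SeriesNumber = header.series_number
        ds.SeriesDescription = header.series_description
        ds.InstanceNumber = k + 1

        ds.PatientName = header.identity.get("patient_name", "")
        ds.PatientID = header.identity.get("patient_id", "")
        ds.PatientBirthDate = header.identity.get("birth_date", "")
        ds.StudyDate = header.identity.get("study_date", "")
        ds.AccessionNumber = header.identity.get("accession", "")
        ds.InstitutionName = header.identity.get("institution", "")
        ds.ReferringPhysicianName = header.identity.get("referring_physician", "")
        if "operators" in header.identity:
            ds.OperatorsName = header.identity["operators"]
        if "institution_address" in header.identity:
            ds.InstitutionAddress = header.identity["institution_address"]
        if "patient_address" in header.identity:
            ds.PatientAddress = header.identity["patient_address"]
        if "other_patient_ids" in header.identity:
            ds.OtherPatientIDs = header.identity["other_patient_ids"]
        if "station_name" in header.identity:
            ds.StationName = header.identity["station_name"]

        ds.ScanningSequence = header.scanning_sequence
        ds.SequenceVariant = "NONE"
        ds.RepetitionTime = str(header.repetition_time)
        if header.echo_time is not None:
            ds.EchoTime = str(header.echo_time)
        if header.inversion_time:
            ds.InversionTime = str(header.inversion_time)
        ds.FlipAngle = str(header.flip_angle)
        ds.MagneticFieldStrength = str(header.field_strength)
        ds.Manufacturer = header.manufacturer
        ds.ManufacturerModelName = header.model
        if header.contrast_agent:
            ds.ContrastBolusAgent = header.contrast_agent
        if header.diffusion_bvalue is not None:
            ds.DiffusionBValue = header.diffusion_bvalue
        if header.n_temporal_positions > 1:
            ds.NumberOfTemporalPositions = header.n_temporal_positions

        for group, element, payload in header.private_tags:
            ds.add_new(pydicom.tag.Tag(group, element), "LO", payload)

        ds.Rows = ny
        ds.Columns = nx
        ds.PixelSpacing = [str(volume.spacing[1]), str(volume.spacing[0])]
        ds.SliceThickness = str(volume.spacing[2])
        ds.SpacingBetweenSlices = str(volume.spacing[2])
        pos = origin + direction[:, 2] * volume.spacing[2] * k
        ds.ImagePositionPatient = [f"{v:.6f}" for v in pos]
        iop = list(direction[:, 0]) + list(direction[:, 1])
        ds.ImageOrientationPatient = [f"{v:.6f}" for v in iop]

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        # [row, col] = [j, i] layout for the PixelData element
        ds.PixelData = np.ascontiguousarray(pixels[:, :, k].T).tobytes()

        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = meta
        path = out_dir / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
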