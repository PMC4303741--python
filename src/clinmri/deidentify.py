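"""Header scrubbing, pseudonymization and registration-based defacing.

Privacy is enforced at two levels: textually, by blanking every
patient-sensitive DICOM element (a subset of the PS3.15 basic
confidentiality profile: names, locations, identifiers and dates) and
removing every private (odd-group) element; and at image level, by
multiplying the volume with a face-exclusion mask carried over from a
registered atlas.  Birth dates are reset to January 1 of the birth year so
age in whole years survives the scrub; ages should nevertheless be computed
*before* scrubbing via :func:`compute_age_at_scan`.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

from .dicom_io import HeaderRecord, ImageVolume
from .registration import (
    AffineTransform,
    RegistrationConfig,
    affine_register,
    apply_transform,
)

__all__ = [
    "ScrubPolicy",
    "IdMap",
    "ExclusionError",
    "DefaceError",
    "scrub_header",
    "compute_age_at_scan",
    "pseudonymize",
    "deface",
    "DEFAULT_SENSITIVE_KEYS",
]

# Identity keys of HeaderRecord.identity that are blanked by default.  The
# study year is retained (ages and acquisition years feed the cohort
# analysis); day and month are truncated.
DEFAULT_SENSITIVE_KEYS = (
    "patient_name",
    "patient_id",
    "accession",
    "institution",
    "institution_address",
    "referring_physician",
    "operators",
    "station_name",
    "patient_address",
    "other_patient_ids",
)


class ExclusionError(RuntimeError):
    """Raised when a request concerns a patient on the exclusion list."""


class DefaceError(RuntimeError):
    """Raised when defacing cannot produce a usable masked image."""


@dataclass(frozen=True)
class ScrubPolicy:
    """What to remove from a header.

    ``sensitive_keys`` are identity fields blanked outright;
    ``remove_all_private`` drops every odd-group element; birth dates are
    reset to January 1 of the birth year and study dates truncated to the
    year.  Applying the policy twice equals applying it once.
    """

    sensitive_keys: tuple[str, ...] = DEFAULT_SENSITIVE_KEYS
    remove_all_private: bool = True
    keep_study_year: bool = True
    uid_salt: str = "clinmri"

    def remap_uid(self, uid: str) -> str:
        """Deterministic keyed remap preserving referential integrity."""
        digest = hashlib.sha256(f"{self.uid_salt}:{uid}".encode()).hexdigest()
        return "2.25." + str(int(digest[:32], 16))


def _reset_birth_date(value: str) -> str:
    value = value.strip()
    if len(value) < 4 or not value[:4].isdigit():
        return ""
    return value[:4] + "0101"


def scrub_header(
    header: HeaderRecord, policy: ScrubPolicy | None = None
) -> tuple[HeaderRecord, list[str]]:
    """Return a scrubbed copy of ``header`` plus an audit list.

    Acquisition parameters (TR/TE/TI, flip angle, spacing, scanner fields)
    are untouched; only identity elements and private tags change.  The
    audit names each modified field but never records the removed value.
    """
    policy = policy or ScrubPolicy()
    out = header.copy()
    audit: list[str] = []

    for key in policy.sensitive_keys:
        if out.identity.get(key):
            out.identity[key] = ""
            audit.append(f"blanked {key}")

    birth = out.identity.get("birth_date", "")
    if birth:
        reset = _reset_birth_date(birth)
        if reset != birth:
            out.identity["birth_date"] = reset
            audit.append("birth_date reset to January 1")
    else:
        audit.append("birth_date absent")

    study = out.identity.get("study_date", "")
    if policy.keep_study_year and len(study) == 8 and study[4:] != "0101":
        out.identity["study_date"] = study[:4] + "0101"
        audit.append("study_date truncated to year")

    if policy.remove_all_private and out.private_tags:
        audit.append(f"removed {len(out.private_tags)} private element(s)")
        out.private_tags = []
    return out, audit


def _parse_date(value: str | date) -> date:
    if isinstance(value, date):
        return value
    value = value.strip().replace("-", "")
    if len(value) != 8 or not value.isdigit():
        raise ValueError(f"unparseable date {value!r}")
    return date(int(value[:4]), int(value[4:6]), int(value[6:8]))


def compute_age_at_scan(birth_date: str | date, study_date: str | date) -> int:
    """Whole years elapsed between birth and scan (floor).

    Must be called before :func:`scrub_header`, which destroys the day and
    month of the birth date.
    """
    born = _parse_date(birth_date)
    scanned = _parse_date(study_date)
    if scanned < born:
        raise ValueError("study date precedes birth date")
    age = scanned.year - born.year
    if (scanned.month, scanned.day) < (born.month, born.day):
        age -= 1
    return age


@dataclass
class IdMap:
    """Bijective hospital-ID <-> pseudo-ID mapping with an exclusion list."""

    pairs: dict[str, str]
    exclusion_list: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("pseudo-IDs collide; mapping is not bijective")
        self._inverse = {v: k for k, v in self.pairs.items()}

    @classmethod
    def from_tsv(
        cls, path: str | Path, exclusions: str | Path | None = None
    ) -> "IdMap":
        """Load a two-column TSV (hospital_id <tab> pseudo_id) and an
        optional one-ID-per-line exclusion file."""
        pairs = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2 and row[0].strip():
                    pairs[row[0].strip()] = row[1].strip()
        excluded = set()
        if exclusions is not None:
            text = Path(exclusions).read_text()
            excluded = {line.strip() for line in text.splitlines() if line.strip()}
        return cls(pairs, excluded)

    def inverse(self, pseudo_id: str) -> str:
        if pseudo_id not in self._inverse:
            raise KeyError("unknown pseudo-ID")
        return self._inverse[pseudo_id]


def pseudonymize(hospital_id: str, id_map: IdMap) -> str:
    """Map a hospital ID to its research pseudo-ID.

    Excluded patients halt the request (the privacy-officer veto); unknown
    IDs are an error rather than being passed through.
    """
    if hospital_id in id_map.exclusion_list:
        raise ExclusionError("request for excluded patient halted")
    if hospital_id not in id_map.pairs:
        raise KeyError("hospital ID not in mapping table")
    return id_map.pairs[hospital_id]


def deface(
    image: ImageVolume,
    atlas_intensity: ImageVolume,
    atlas_face_mask: np.ndarray,
    config: RegistrationConfig | None = None,
    transform: AffineTransform | None = None,
) -> tuple[ImageVolume, AffineTransform]:
    """Zero the facial region of ``image`` via a registered atlas mask.

    The atlas (moving) is affinely registered to the subject (fixed); the
    binary keep-mask (1 = keep, 0 = face) is resampled nearest-neighbour
    through the same transform and multiplied into the image, so kept
    voxels are bit-identical to the input.  A precomputed ``transform``
    skips the registration (e.g. when the same atlas was already registered
    for another stage).
    """
    config = config or RegistrationConfig()
    mask = np.asarray(atlas_face_mask)
    if mask.shape != atlas_intensity.shape:
        raise ValueError("face mask must live on the atlas grid")
    if not np.isin(mask, [0, 1]).all():
        raise ValueError("face mask must be binary (1 = keep, 0 = face)")

    if transform is None:
        # affine_register guarantees final MI >= initial MI by construction
        transform, _ = affine_register(atlas_intensity, image, config)
    mask_vol = ImageVolume(
        mask.astype(np.float64),
        atlas_intensity.spacing,
        atlas_intensity.origin,
        atlas_intensity.direction,
    )
    warped = apply_transform(mask_vol, transform, image, interpolation="nearest")
    keep = warped.data > 0.5
    if not keep.any():
        raise DefaceError("registered face mask removed the whole image")
    return image.with_data(np.where(keep, image.data, 0.0)), transform
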