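"""Quality assurance: sequence classification, series selection, FOV check.

Clinical archives name series inconsistently, so the MR contrast (T1w, T2w,
PDw, ...) is inferred from the physics in the header — scanning sequence
code, repetition/echo/inversion time and flip angle — through an explicit,
overridable decision table.  A field-of-view check registers an atlas brain
mask to the subject and excludes the scan when more than 20 % of any outer
image plane is labelled brain, the signature of a truncated head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dicom_io import HeaderRecord, ImageVolume, SeriesRead, voxel_volume
from .registration import (
    AffineTransform,
    RegistrationConfig,
    RegistrationError,
    affine_register,
    apply_transform,
)

__all__ = [
    "SequenceClass",
    "QaDecision",
    "SequenceRule",
    "DEFAULT_DECISION_TABLE",
    "FOV_BRAIN_FRACTION_LIMIT",
    "classify_sequence",
    "select_best_series",
    "check_contrast",
    "check_fov",
    "boundary_brain_fractions",
]

# Strict "more than 20 %" rule for brain voxels on an outer plane.
FOV_BRAIN_FRACTION_LIMIT = 0.20


@dataclass(frozen=True)
class SequenceClass:
    """Inferred MR contrast plus the decision-table row that fired."""

    value: str  # T1w, T2w, PDw, DWI, fMRI, other, unknown
    rule_fired: str


@dataclass(frozen=True)
class QaDecision:
    """Outcome of the image-level QA checks for one series."""

    passed: bool
    reasons: tuple[str, ...] = ()
    boundary_brain_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when reasons is empty")


@dataclass(frozen=True)
class SequenceRule:
    """One row of the decision table; ``None`` bounds are unconstrained."""

    name: str
    result: str
    sequence: str | None = None  # SE/GR/EP code required, if any
    tr_lt: float | None = None
    tr_ge: float | None = None
    te_lt: float | None = None
    te_ge: float | None = None
    ti_positive: bool | None = None
    flip_ge: float | None = None
    needs_bvalue: bool = False
    min_temporal_positions: int | None = None

    def matches(self, h: HeaderRecord) -> bool:
        if self.needs_bvalue:
            return h.diffusion_bvalue is not None
        if self.min_temporal_positions is not None:
            return (
                h.scanning_sequence == (self.sequence or "EP")
                and h.n_temporal_positions >= self.min_temporal_positions
            )
        if self.sequence is not None and h.scanning_sequence != self.sequence:
            return False
        if h.echo_time is None:
            return False  # numeric rules need TE
        if self.tr_lt is not None and not h.repetition_time < self.tr_lt:
            return False
        if self.tr_ge is not None and not h.repetition_time >= self.tr_ge:
            return False
        if self.te_lt is not None and not h.echo_time < self.te_lt:
            return False
        if self.te_ge is not None and not h.echo_time >= self.te_ge:
            return False
        if self.ti_positive is not None:
            if self.ti_positive != (h.inversion_time > 0):
                return False
        if self.flip_ge is not None and not h.flip_angle >= self.flip_ge:
            return False
        return True


# Declared defaults (textbook-style thresholds, config-overridable): rules
# fire top to bottom, first match wins.
DEFAULT_DECISION_TABLE: tuple[SequenceRule, ...] = (
    SequenceRule("diffusion-b-value", "DWI", needs_bvalue=True),
    SequenceRule("ep-temporal-series", "fMRI", sequence="EP",
                 min_temporal_positions=10),
    SequenceRule("gr-inversion-prepared", "T1w", sequence="GR",
                 ti_positive=True),
    SequenceRule("gr-short-te-spoiled", "T1w", sequence="GR",
                 ti_positive=False, te_lt=10.0, flip_ge=8.0),
    SequenceRule("se-short-tr-short-te", "T1w", sequence="SE",
                 tr_lt=1000.0, te_lt=30.0),
    SequenceRule("se-long-tr-long-te", "T2w", sequence="SE",
                 tr_ge=2000.0, te_ge=80.0),
    SequenceRule("se-long-tr-short-te", "PDw", sequence="SE",
                 tr_ge=2000.0, te_lt=30.0),
)


def classify_sequence(
    header: HeaderRecord,
    table: tuple[SequenceRule, ...] = DEFAULT_DECISION_TABLE,
) -> SequenceClass:
    """Classify a series by its acquisition parameters.

    Deterministic and total: when no row fires the class is ``unknown``
    (a value, not an error — e.g. a missing echo time).
    """
    for rule in table:
        if rule.matches(header):
            return SequenceClass(rule.result, rule.name)
    return SequenceClass("unknown", "no-rule-fired")


def check_contrast(header: HeaderRecord) -> bool:
    """True (exclude) iff a contrast agent is recorded (whitespace = none)."""
    return bool(header.contrast_agent.strip())


def select_best_series(
    series: list[SeriesRead],
    wanted: set[str],
    table: tuple[SequenceRule, ...] = DEFAULT_DECISION_TABLE,
) -> dict[str, SeriesRead | None]:
    """Pick the highest-resolution series for each wanted contrast class.

    Resolution is voxel volume (smaller is better); ties go to the larger
    in-plane matrix, then to the lowest series number.  Classes with no
    candidate map to ``None``.
    """
    if not series:
        raise ValueError("no series to select from")
    chosen: dict[str, SeriesRead | None] = {cls: None for cls in wanted}
    candidates: dict[str, list[SeriesRead]] = {cls: [] for cls in wanted}
    for item in series:
        cls = classify_sequence(item.header, table).value
        if cls in candidates:
            candidates[cls].append(item)

    def sort_key(item: SeriesRead):
        h = item.header
        return (
            voxel_volume(h),
            -(h.matrix[0] * h.matrix[1]),
            h.series_number,
        )

    for cls, items in candidates.items():
        if items:
            chosen[cls] = min(items, key=sort_key)
    return chosen


def boundary_brain_fractions(brain_mask: np.ndarray) -> tuple[float, ...]:
    """Brain-voxel fraction on each of the six outer planes of the grid.

    Order: (i=0, i=-1, j=0, j=-1, k=0, k=-1).
    """
    m = np.asarray(brain_mask) > 0
    planes = (m[0], m[-1], m[:, 0], m[:, -1], m[:, :, 0], m[:, :, -1])
    return tuple(float(p.mean()) for p in planes)


def check_fov(
    subject: ImageVolume,
    atlas_brain_mask: np.ndarray,
    atlas_intensity: ImageVolume,
    config: RegistrationConfig | None = None,
    transform: AffineTransform | None = None,
) -> QaDecision:
    """Exclude scans whose brain extends past the image boundary.

    The atlas is affinely registered to the subject, its brain mask carried
    over nearest-neighbour, and the brain fraction measured on all six outer
    planes; strictly more than 20 % on any plane excludes the scan.  A
    registration failure yields an ``unreadable`` decision rather than an
    exception.
    """
    config = config or RegistrationConfig()
    mask = np.asarray(atlas_brain_mask)
    if mask.shape != atlas_intensity.shape:
        raise ValueError("brain mask must live on the atlas grid")
    try:
        if transform is None:
            transform, _ = affine_register(atlas_intensity, subject, config)
        mask_vol = ImageVolume(
            mask.astype(np.float64),
            atlas_intensity.spacing,
            atlas_intensity.origin,
            atlas_intensity.direction,
        )
        warped = apply_transform(mask_vol, transform, subject, "nearest")
    except RegistrationError:
        return QaDecision(False, ("unreadable",))
    fractions = boundary_brain_fractions(warped.data)
    if max(fractions) > FOV_BRAIN_FRACTION_LIMIT:
        return QaDecision(False, ("incomplete_fov",), fractions)
    return QaDecision(True, (), fractions)
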