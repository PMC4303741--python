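"""End-to-end orchestration: retrieve, de-identify, QA, segment, account.

Each examination runs independently through the stage chain
read -> scrub/deface -> QA -> segment -> volumes, stopping at the first
failure with a recorded reason; a batch is the order-invariant collection
of per-exam results plus the step-wise accounting table.  Retrieval is
abstracted behind a small interface: the filesystem implementation reads
DICOM directories, while the DICOM-network variant (C-FIND/C-MOVE against a
hospital archive) is deliberately a stub that raises until configured.

No identity field from an input header may appear in any output file; exam
outputs are keyed by pseudo-ID and headers are scrubbed before anything is
written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import qa as qa_mod
from .cohort import success_rate_report
from .deidentify import (
    ExclusionError,
    IdMap,
    ScrubPolicy,
    compute_age_at_scan,
    deface,
    pseudonymize,
    scrub_header,
)
from .dicom_io import DicomReadError, read_series, save_nifti
from .phantom import AtlasSet
from .registration import RegistrationConfig, affine_register
from .segmentation import (
    BiasConfig,
    KnnConfig,
    segment_examination,
)

__all__ = [
    "PipelineConfig",
    "ExaminationResult",
    "FilesystemRetrieval",
    "NetworkRetrieval",
    "STAGES",
    "run_examination",
    "run_batch",
]

log = logging.getLogger("clinmri.pipeline")

STAGES = ("retrieved", "deidentified", "qa", "segmented", "volumes")


class FilesystemRetrieval:
    """Retrieve an examination from a directory of DICOM files."""

    def fetch(self, exam_dir: str | Path):
        return read_series(exam_dir)


class NetworkRetrieval:
    """Placeholder for DICOM network retrieval (C-FIND / C-MOVE)."""

    def fetch(self, exam_dir):
        raise NotImplementedError("DICOM network retrieval is not configured")


@dataclass
class PipelineConfig:
    """Everything one batch run needs; serialisable to/from YAML."""

    output_dir: str = "out"
    seed: int = 0
    stop_after: str = "volumes"  # last stage to execute
    deface_enabled: bool = True
    wanted_sequences: tuple[str, ...] = ("T1w", "PDw", "T2w")
    mask_threshold: float = 0.8
    scrub: ScrubPolicy = field(default_factory=ScrubPolicy)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)
    id_map: IdMap | None = None
    save_volumes: bool = True

    def __post_init__(self) -> None:
        if self.stop_after not in STAGES:
            raise ValueError(f"stop_after must be one of {STAGES}")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "stop_after": self.stop_after,
            "deface_enabled": self.deface_enabled,
            "wanted_sequences": list(self.wanted_sequences),
            "mask_threshold": self.mask_threshold,
            "save_volumes": self.save_volumes,
            "scrub": {
                "sensitive_keys": list(self.scrub.sensitive_keys),
                "remove_all_private": self.scrub.remove_all_private,
                "keep_study_year": self.scrub.keep_study_year,
                "uid_salt": self.scrub.uid_salt,
            },
            "registration": dataclasses.asdict(self.registration),
            "knn": dataclasses.asdict(self.knn),
            "bias": dataclasses.asdict(self.bias),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        scrub = payload.pop("scrub", {})
        if "sensitive_keys" in scrub:
            scrub["sensitive_keys"] = tuple(scrub["sensitive_keys"])
        reg = payload.pop("registration", {})
        for key in ("shrink_factors", "smoothing_sigmas", "nonrigid_mesh"):
            if key in reg:
                reg[key] = tuple(reg[key])
        knn = payload.pop("knn", {})
        bias = payload.pop("bias", {})
        if "wanted_sequences" in payload:
            payload["wanted_sequences"] = tuple(payload["wanted_sequences"])
        return cls(
            scrub=ScrubPolicy(**scrub),
            registration=RegistrationConfig(**reg),
            knn=KnnConfig(**knn),
            bias=BiasConfig(**bias),
            **payload,
        )


@dataclass
class ExaminationResult:
    """Terminal state and artefacts of one examination run."""

    pseudo_id: str
    terminal_stage: str
    failure_reason: str | None = None
    biomarkers: dict | None = None
    qa_fractions: tuple[float, ...] = ()
    log_lines: list[str] = field(default_factory=list)
    artifact_paths: list[str] = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return self.failure_reason is None

    def __post_init__(self) -> None:
        # "selected" marks an exam that failed before any stage completed
        if self.terminal_stage not in STAGES + ("selected",):
            raise ValueError(f"invalid terminal stage {self.terminal_stage!r}")
        if self.failure_reason is None and self.terminal_stage == "selected":
            raise ValueError("a completed result must have reached a stage")


def _stage_index(stage: str) -> int:
    return STAGES.index(stage)


def run_examination(
    exam_dir: str | Path,
    atlases: AtlasSet,
    config: PipelineConfig,
    retrieval=None,
) -> ExaminationResult:
    """Run one examination through the stage chain.

    Every stage error is captured into the result (the batch never
    crashes); the result's ``terminal_stage`` is the last stage completed.
    """
    retrieval = retrieval or FilesystemRetrieval()
    exam_dir = Path(exam_dir)
    lines: list[str] = []
    stop = _stage_index(config.stop_after)
    out_dir: Path | None = None

    def finish(pseudo, stage, reason=None, **kw):
        if reason:
            lines.append(f"failed at {stage}: {reason}")
        if out_dir is not None:
            (out_dir / "exam.log").write_text("\n".join(lines) + "\n")
        return ExaminationResult(pseudo, stage, reason, log_lines=lines, **kw)

    # -- retrieve
    try:
        series = retrieval.fetch(exam_dir)
    except DicomReadError as exc:
        return finish("", "selected", f"unreadable: {exc}")
    readable = [s for s in series if s.readable]
    lines.append(f"retrieved {len(series)} series ({len(readable)} readable)")
    if not readable:
        return finish("", "selected", "unreadable: no consistent series")

    # -- pseudonymize + scrub (before anything is written or logged further)
    raw_header = readable[0].header
    hospital_id = raw_header.identity.get("patient_id", "")
    if config.id_map is not None:
        try:
            pseudo_id = pseudonymize(hospital_id, config.id_map)
        except ExclusionError:
            return finish("", "selected", "excluded: on exclusion list")
        except KeyError:
            return finish("", "selected", "unknown hospital ID")
    else:
        pseudo_id = exam_dir.name

    age = None
    birth = raw_header.identity.get("birth_date", "")
    study = raw_header.identity.get("study_date", "")
    if birth and study:
        try:
            age = compute_age_at_scan(birth, study)
        except ValueError:
            lines.append("age could not be computed")

    scrubbed = []
    for item in readable:
        header, audit = scrub_header(item.header, config.scrub)
        scrubbed.append((item.volume, header))
        lines.extend(f"scrub[{header.series_number}]: {entry}" for entry in audit)

    out_dir = Path(config.output_dir) / pseudo_id
    out_dir.mkdir(parents=True, exist_ok=True)

    if _stage_index("deidentified") > stop:
        return finish(pseudo_id, "retrieved")

    # -- deface (atlas 0 is the defacing template)
    atlas0 = atlases.atlases[0]
    atlas_transform = None
    if config.deface_enabled:
        volume0, header0 = scrubbed[0]
        defaced, atlas_transform = deface(
            volume0,
            atlas0.intensity,
            atlas0.face_exclusion_mask,
            config.registration,
        )
        scrubbed[0] = (defaced, header0)
        lines.append("defaced series 0 via registered atlas mask")

    # the de-identified (scrubbed + defaced) series is itself an artefact
    from .phantom import write_dicom_series

    for i, (volume, header) in enumerate(scrubbed):
        write_dicom_series(
            volume,
            header,
            out_dir / f"dicom_{i}",
            series_uid_key=config.scrub.remap_uid(f"{pseudo_id}/{i}"),
        )
    if config.save_volumes:
        path = out_dir / "deidentified.nii.gz"
        save_nifti(scrubbed[0][0], path)
    if _stage_index("qa") > stop:
        return finish(pseudo_id, "deidentified")

    # -- quality assurance
    from .dicom_io import SeriesRead

    as_series = [SeriesRead(v, h) for v, h in scrubbed]
    chosen = qa_mod.select_best_series(as_series, set(config.wanted_sequences))
    best = next(
        (chosen[cls] for cls in config.wanted_sequences if chosen.get(cls)), None
    )
    if best is None:
        return finish(pseudo_id, "deidentified", "unsupported_sequence")
    if qa_mod.check_contrast(best.header):
        return finish(pseudo_id, "deidentified", "contrast_agent")
    decision = qa_mod.check_fov(
        best.volume,
        atlas0.intracranial_mask,
        atlas0.intensity,
        config.registration,
        transform=atlas_transform,
    )
    lines.append(
        "qa fractions: "
        + ", ".join(f"{f:.3f}" for f in decision.boundary_brain_fractions)
    )
    if not decision.passed:
        return finish(
            pseudo_id,
            "deidentified",
            decision.reasons[0],
            qa_fractions=decision.boundary_brain_fractions,
        )
    if _stage_index("segmented") > stop:
        return finish(
            pseudo_id, "qa", qa_fractions=decision.boundary_brain_fractions
        )

    # -- segmentation + volumes
    try:
        labels, record = segment_examination(
            best.volume,
            atlases,
            config.registration,
            dataclasses.replace(config.knn, seed=config.seed),
            config.bias,
            config.mask_threshold,
            pseudo_id=pseudo_id,
        )
    except Exception as exc:  # any stage error becomes a recorded failure
        return finish(pseudo_id, "qa", f"segmentation failed: {exc}")
    record.age = age
    record.sequence = qa_mod.classify_sequence(best.header).value
    record.scanner_model = best.header.model
    record.field_strength = best.header.field_strength

    artifacts = []
    if config.save_volumes:
        label_path = out_dir / "labels.nii.gz"
        save_nifti(labels, label_path)
        artifacts.append(str(label_path))
    record_path = out_dir / "biomarkers.json"
    record_path.write_text(json.dumps(record.as_dict(), indent=2, default=str))
    artifacts.append(str(record_path))
    (out_dir / "exam.log").write_text("\n".join(lines) + "\n")
    return finish(
        pseudo_id,
        "volumes",
        biomarkers=record.as_dict(),
        qa_fractions=decision.boundary_brain_fractions,
        artifact_paths=artifacts,
    )


def run_batch(
    exam_dirs: list[str | Path],
    atlases: AtlasSet,
    config: PipelineConfig,
    group: str = "all",
):
    """Run every examination independently and account for the losses.

    Returns ``(results, cohort_df, accounting_df)``; the cohort table is
    sorted by pseudo-ID, so results are invariant to the order of
    ``exam_dirs``.
    """
    import pandas as pd

    if not exam_dirs:
        raise ValueError("empty batch")
    results = [run_examination(d, atlases, config) for d in exam_dirs]

    reached = {stage: 0 for stage in STAGES}
    for res in results:
        if res.terminal_stage == "selected":
            continue  # failed before anything completed
        for stage in STAGES[: _stage_index(res.terminal_stage) + 1]:
            reached[stage] += 1
    counts = {
        group: {
            "selected": len(results),
            "retrieved": reached["retrieved"],
            "qa_passed": reached["qa"],
            "biomarker_ok": reached["volumes"],
        }
    }
    accounting = success_rate_report(counts)

    rows = [res.biomarkers for res in results if res.biomarkers]
    cohort = pd.DataFrame(rows)
    if not cohort.empty:
        cohort = cohort.sort_values("pseudo_id").reset_index(drop=True)
        cohort_path = Path(config.output_dir) / "cohort.csv"
        cohort_path.parent.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(cohort_path, index=False)
    return results, cohort, accounting
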