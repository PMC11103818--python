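"""End-to-end orchestration: raw tables in, classified courses and flow out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohort import ExclusionFlow, apply_exclusions, attribute_exclusions, classify_courses
from .config import RunConfig
from .courses import assemble_courses, partition_therapeutic, resolve_indications
from .records import AdmissionRecord, PrescriptionRecord, TreatmentCourse

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    included: list[TreatmentCourse]
    all_courses: list[TreatmentCourse]  # every assembled course, exclusion_reason set
    flow: ExclusionFlow
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    prescriptions: list[PrescriptionRecord],
    admissions: list[AdmissionRecord],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run therapeutic filtering, course assembly, indication resolution,
    cohort classification and the exclusion cascade, logging stage counts."""
    config = config or RunConfig()
    parts = partition_therapeutic(prescriptions, config.prophylaxis)
    stage_counts = {
        "raw_prescriptions": len(prescriptions),
        "removed_non_j01": len(parts["non_j01"]),
        "removed_labeled_prophylaxis": len(parts["labeled_prophylaxis"]),
        "removed_presumed_prophylaxis": len(parts["presumed_prophylaxis"]),
        "therapeutic_prescriptions": len(parts["kept"]),
    }
    courses = assemble_courses(parts["kept"], gap_hours=config.thresholds.gap_hours)
    stage_counts["assembled_courses"] = len(courses)

    # partition check: no prescription lost or duplicated
    member_ids = [rx.prescription_id for c in courses for rx in c.member_prescriptions]
    if sorted(member_ids) != sorted(rx.prescription_id for rx in parts["kept"]):
        raise AssertionError("course assembly lost or duplicated prescriptions")

    courses = [resolve_indications(c) for c in courses]
    courses = classify_courses(courses, admissions, config.thresholds)
    processed = attribute_exclusions(courses, admissions, config.thresholds)
    included, flow = apply_exclusions(courses, admissions, config.thresholds)
    stage_counts["included_courses"] = len(included)
    for stage, n in stage_counts.items():
        log.info("stage %s: %d", stage, n)
    return PipelineResult(
        included=included, all_courses=processed, flow=flow, stage_counts=stage_counts
    )
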