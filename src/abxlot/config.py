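"""Tunable thresholds of the surveillance method, with their published defaults.

Every rule the pipeline applies — the 24 h linkage gap, the 48 h
community/hospital boundary, the 12 h minimum admission, the 45 day course
cap, the pediatric age cut and the presumed-prophylaxis drug/duration/dose
rules — lives here so that a deployment can override them from one YAML
block while the defaults reproduce the published method exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["ProphylaxisRuleSet", "Thresholds", "RunConfig", "normalize_drug"]


def normalize_drug(name: str) -> str:
    return name.strip().lower()


#: Accepted spellings of trimethoprim/sulfamethoxazole.
COTRIMOXAZOLE_NAMES = frozenset(
    {
        "trimethoprim/sulfamethoxazole",
        "sulfamethoxazole/trimethoprim",
        "co-trimoxazole",
        "cotrimoxazole",
    }
)


class ProphylaxisRuleSet(BaseModel):
    """Drug-specific duration (and, for co-trimoxazole, dose) thresholds that
    reclassify an unlabeled prescription as presumed prophylaxis.

    The listed agents are typical long-term prophylactic antibiotics; a
    prescription of one of them running longer than ``long_term_threshold_days``
    is presumed prophylactic.  Co-trimoxazole is presumed prophylactic at low
    daily dose (<= 480 mg) beyond 14 days and at higher dose beyond 50 days.
    """

    model_config = ConfigDict(frozen=True)

    long_term_drugs: frozenset[str] = frozenset(
        {
            "azithromycin",
            "clarithromycin",
            "doxycycline",
            "erythromycin",
            "fosfomycin",
            "nitrofurantoin",
            "pheneticillin",
            "trimethoprim",
        }
    )
    long_term_threshold_days: int = 28
    cotrimoxazole_low_dose_mg: float = 480.0
    cotrimoxazole_low_dose_threshold_days: int = 14
    cotrimoxazole_high_dose_threshold_days: int = 50

    @model_validator(mode="after")
    def _check(self) -> "ProphylaxisRuleSet":
        if min(
            self.long_term_threshold_days,
            self.cotrimoxazole_low_dose_threshold_days,
            self.cotrimoxazole_high_dose_threshold_days,
        ) <= 0 or self.cotrimoxazole_low_dose_mg <= 0:
            raise ValueError("all prophylaxis thresholds must be strictly positive")
        if self.cotrimoxazole_low_dose_threshold_days >= self.cotrimoxazole_high_dose_threshold_days:
            raise ValueError("low-dose threshold must be below the high-dose threshold")
        return self

    def normalized_drugs(self) -> frozenset[str]:
        return frozenset(normalize_drug(d) for d in self.long_term_drugs)


class Thresholds(BaseModel):
    """Temporal and demographic cut-offs of the surveillance method."""

    model_config = ConfigDict(frozen=True)

    gap_hours: float = 24.0  # max prescription-linkage gap within a course
    ca_ha_boundary_hours: float = 48.0  # CA if started earlier than this after admit
    min_admission_hours: float = 12.0  # shorter stays do not count as hospitalization
    max_course_days: int = 45  # longer courses are excluded from analysis
    pediatric_age_years: float = 18.0  # younger patients are excluded

    @model_validator(mode="after")
    def _check(self) -> "Thresholds":
        vals = (
            self.gap_hours,
            self.ca_ha_boundary_hours,
            self.min_admission_hours,
            self.max_course_days,
            self.pediatric_age_years,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be strictly positive")
        return self


class RunConfig(BaseModel):
    """Complete pipeline configuration: thresholds, prophylaxis rules, seed."""

    model_config = ConfigDict(frozen=True)

    thresholds: Thresholds = Thresholds()
    prophylaxis: ProphylaxisRuleSet = ProphylaxisRuleSet()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        # frozensets are not YAML-representable
        data["prophylaxis"]["long_term_drugs"] = sorted(
            self.prophylaxis.long_term_drugs
        )
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
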