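"""Study-window and effectiveness-criteria configuration.

``StudyConfig`` pins the need population: the study-year window, the
minimum screening age (completed years at a reference date), the included
province codes, and the ICD-10 prefixes that count as hypertension
evidence.  ``CriteriaConfig`` pins the effectiveness-criteria parameters:
the confirmation and treatment windows and the BP-control cutoffs.

Both load from a single YAML file with top-level ``study`` and
``criteria`` sections whose keys match the field names exactly.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

HT_ICD10_PREFIXES = ("I10", "I11", "I12", "I13", "I14", "I15")


class StudyConfig(BaseModel):
    """Parameters defining the screening target (need) population."""

    study_year_start: dt.date = dt.date(2013, 1, 1)
    study_year_end: dt.date = dt.date(2013, 12, 31)
    min_age_years: int = Field(default=15, ge=0)
    included_provinces: frozenset[int] = frozenset(range(1, 77))
    ht_icd10_prefixes: tuple[str, ...] = HT_ICD10_PREFIXES
    reference_date_for_age: Optional[dt.date] = None

    @model_validator(mode="after")
    def _window_ordered(self):
        if not self.study_year_start < self.study_year_end:
            raise ValueError("study_year_start must precede study_year_end")
        return self

    @property
    def age_reference_date(self) -> dt.date:
        """Age is measured in completed years at this date (default: window start)."""
        return self.reference_date_for_age or self.study_year_start


class CriteriaConfig(BaseModel):
    """Parameters of the per-subgroup effectiveness criteria.

    confirmation_window_days: a suspected-HT screening counts as confirmed
        when a repeat BP reading falls in (0, window] days after the
        initial screening (day 0 itself does not count).
    treatment_window_days: treatment is timely when a treatment-start
        event falls within this many days on/after the diagnosis date.
    bp_control_*_max: exclusive upper bounds for "under control"
        (SBP < 140 and DBP < 90 mmHg by default).
    q_scoring: ``binary_subgroup`` scores Q per BP subgroup only;
        ``strict`` additionally requires diagnosed persons to meet all
        four diagnosed-cascade criteria for Q = 1.
    """

    confirmation_window_days: int = Field(default=60, gt=0)
    treatment_window_days: int = Field(default=183, gt=0)
    bp_control_sbp_max: int = Field(default=140, gt=0)
    bp_control_dbp_max: int = Field(default=90, gt=0)
    cvd_assessment_required_lipids: frozenset[str] = frozenset(
        {"total_chol", "ldl", "hdl"}
    )
    q_scoring: Literal["binary_subgroup", "strict"] = "binary_subgroup"

    @field_validator("cvd_assessment_required_lipids")
    @classmethod
    def _known_lipids(cls, v):
        unknown = set(v) - {"total_chol", "ldl", "hdl"}
        if unknown:
            raise ValueError(f"unknown lipid fields: {sorted(unknown)}")
        return v


def load_configs(path) -> tuple[StudyConfig, CriteriaConfig]:
    """Load ``study`` and ``criteria`` sections from a YAML file.

    Missing sections or keys fall back to defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    study = StudyConfig(**(data.get("study") or {}))
    criteria = CriteriaConfig(**(data.get("criteria") or {}))
    return study, criteria
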