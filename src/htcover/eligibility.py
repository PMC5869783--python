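"""Need population (N): who is in the hypertension-screening target group.

A person is eligible (N = 1) when all of the following hold at the study
window: completed age at the reference date is at least ``min_age_years``
(15 by default), the province of record is in the included set, the person
is in the civil registry, and there is no hypertension evidence dated
strictly before the study window start.  HT evidence is either a registry
entry with condition ``hypertension`` or a diagnosis whose ICD-10 code
starts with one of the configured prefixes (I10–I15 by default).

A diagnosis *during* the study year does not exclude: such a person stays
in the screening target and becomes a newly-diagnosed cascade member.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig
from .records import RecordBundle

EXCLUSION_REASONS = (
    "under_age",
    "prior_ht_diagnosis",
    "not_in_registry",
    "excluded_province",
    "missing_birth_date",
)


def completed_years(birth_dates: pd.Series, reference_date) -> pd.Series:
    """Completed calendar years between birth date and reference date."""
    birth = pd.to_datetime(birth_dates)
    ref = pd.Timestamp(reference_date)
    years = ref.year - birth.dt.year
    before_birthday = (birth.dt.month > ref.month) | (
        (birth.dt.month == ref.month) & (birth.dt.day > ref.day)
    )
    return years - before_birthday.astype("int64")


def determine_eligibility(
    bundle: RecordBundle,
    config: StudyConfig,
    on_missing_birth_date: str = "error",
) -> pd.DataFrame:
    """One assignment per person: ``person_id``, ``eligible``, ``exclusion_reason``.

    ``on_missing_birth_date``: ``"error"`` raises on a NaT birth date
    (strict), ``"exclude"`` marks the person ineligible with reason
    ``missing_birth_date`` (permissive).
    """
    if on_missing_birth_date not in ("error", "exclude"):
        raise ValueError(f"unknown on_missing_birth_date {on_missing_birth_date!r}")
    persons = bundle.persons
    missing_birth = persons["birth_date"].isna()
    if missing_birth.any() and on_missing_birth_date == "error":
        bad = persons.loc[missing_birth, "person_id"].tolist()[:5]
        raise ValueError(f"persons with missing birth_date: {bad} ...")

    age = completed_years(persons["birth_date"], config.age_reference_date)
    under_age = (age < config.min_age_years).fillna(False).astype(bool)
    off_province = ~persons["province_code"].isin(config.included_provinces)
    not_registered = ~persons["in_civil_registry"].fillna(False).astype(bool)

    start = pd.Timestamp(config.study_year_start)
    prior_ids: set = set()
    reg = bundle.registry
    if len(reg):
        prior_reg = reg[
            reg["condition"].isin(["hypertension"]) & (reg["registration_date"] < start)
        ]
        prior_ids |= set(prior_reg["person_id"])
    dx = bundle.diagnoses
    if len(dx):
        codes = dx["icd10_code"].astype("string").str.upper()
        is_ht = codes.str.startswith(tuple(config.ht_icd10_prefixes)).fillna(False)
        prior_dx = dx[is_ht.astype(bool) & (dx["event_date"] < start)]
        prior_ids |= set(prior_dx["person_id"])
    prior_ht = persons["person_id"].isin(prior_ids)

    # first applicable reason wins, in this documented priority order
    reason = np.select(
        [
            missing_birth.to_numpy(),
            under_age.to_numpy(),
            off_province.to_numpy(),
            not_registered.to_numpy(),
            prior_ht.to_numpy(),
        ],
        ["missing_birth_date", "under_age", "excluded_province",
         "not_in_registry", "prior_ht_diagnosis"],
        default="",
    )
    out = pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy(),
            "eligible": reason == "",
            "exclusion_reason": pd.Series(reason).replace("", pd.NA).to_numpy(),
        }
    )
    return out
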