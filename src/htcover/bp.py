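"""Blood-pressure subgroup classification and initial-screening selection.

Cutoffs (mmHg): normotension SBP < 120 and DBP < 80; pre-hypertension
SBP 120–139 and/or DBP 80–89; suspected hypertension SBP >= 140 and/or
DBP >= 90.  The "and/or" wording is implemented as precedence — a reading
is suspected HT whenever either threshold is crossed, else pre-HT
whenever either lower threshold is crossed, else normotension — which
partitions the whole physiologic grid into exactly three classes.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .records import DBP_RANGE, SBP_RANGE, RecordBundle


class BPCategory(str, enum.Enum):
    NORMOTENSION = "normotension"
    PRE_HT = "pre_ht"
    SUSPECTED_HT = "suspected_ht"


@dataclasses.dataclass(frozen=True)
class SubgroupAssignment:
    """Utilization (U) and BP subgroup for one eligible person.

    ``screened`` is the person-level U indicator.  When screened, the
    initial screening is the earliest in-window BP measurement and its
    raw values are kept for the BP-control comparison downstream.
    """

    person_id: str
    screened: bool
    initial_screening_date: Optional[pd.Timestamp] = None
    sbp: Optional[int] = None
    dbp: Optional[int] = None
    category: Optional[BPCategory] = None

    def __post_init__(self):
        if self.screened != (self.category is not None) or self.screened != (
            self.initial_screening_date is not None
        ):
            raise ValueError("category/date present iff screened")


def classify_bp(sbp: int, dbp: int) -> BPCategory:
    """Classify a single (SBP, DBP) reading; inputs must be physiologic."""
    if not (SBP_RANGE[0] <= sbp <= SBP_RANGE[1]):
        raise ValueError(f"sbp {sbp} outside physiologic range {SBP_RANGE}")
    if not (DBP_RANGE[0] <= dbp <= DBP_RANGE[1]):
        raise ValueError(f"dbp {dbp} outside physiologic range {DBP_RANGE}")
    if dbp >= sbp:
        raise ValueError(f"dbp {dbp} must be below sbp {sbp}")
    if sbp >= 140 or dbp >= 90:
        return BPCategory.SUSPECTED_HT
    if sbp >= 120 or dbp >= 80:
        return BPCategory.PRE_HT
    return BPCategory.NORMOTENSION


def classify_bp_values(sbp, dbp) -> np.ndarray:
    """Vectorized classification; returns an array of category strings."""
    sbp = np.asarray(sbp)
    dbp = np.asarray(dbp)
    return np.select(
        [(sbp >= 140) | (dbp >= 90), (sbp >= 120) | (dbp >= 80)],
        [BPCategory.SUSPECTED_HT.value, BPCategory.PRE_HT.value],
        default=BPCategory.NORMOTENSION.value,
    )


def assign_subgroups(
    bundle: RecordBundle,
    eligibility: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Initial screening and BP subgroup for every eligible person.

    Returns one row per eligible person with columns ``person_id``,
    ``screened``, ``initial_screening_date``, ``sbp``, ``dbp``,
    ``category``.  The initial screening is the earliest screening record
    inside the study window; same-day ties break by higher SBP, then
    higher DBP, then input row order.  Follow-up BP service events never
    count as the initial screening.  Ineligible persons get no row.
    """
    eligible_ids = eligibility.loc[eligibility["eligible"], "person_id"]
    start = pd.Timestamp(config.study_year_start)
    end = pd.Timestamp(config.study_year_end)

    scr = bundle.screenings
    in_window = (scr["event_date"] >= start) & (scr["event_date"] <= end)
    scr = scr.loc[in_window & scr["person_id"].isin(set(eligible_ids))].copy()
    scr["_row"] = np.arange(len(scr))
    scr = scr.sort_values(
        ["person_id", "event_date", "sbp", "dbp", "_row"],
        ascending=[True, True, False, False, True],
        kind="stable",
    )
    initial = scr.drop_duplicates("person_id", keep="first")

    out = pd.DataFrame({"person_id": eligible_ids.to_numpy()})
    out = out.merge(
        initial[["person_id", "event_date", "sbp", "dbp"]], on="person_id", how="left"
    )
    out = out.rename(columns={"event_date": "initial_screening_date"})
    out["screened"] = out["initial_screening_date"].notna()
    cat = np.full(len(out), None, dtype=object)
    m = out["screened"].to_numpy()
    if m.any():
        cat[m] = classify_bp_values(
            out.loc[m, "sbp"].astype(int).to_numpy(),
            out.loc[m, "dbp"].astype(int).to_numpy(),
        )
    out["category"] = cat
    return out[
        ["person_id", "screened", "initial_screening_date", "sbp", "dbp", "category"]
    ]
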