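"""Effectiveness criteria (Q) and the newly-diagnosed care cascade.

Each screened person is scored on the criterion of their BP subgroup:

* normotension — the screening itself is the intervention, so Q = 1;
* pre-HT — an HT & CVD risk-assessment service inside the study window,
  on or after the initial screening date;
* suspected HT — a repeat BP measurement (a later screening record or a
  follow-up BP event) strictly after the initial screening and within the
  confirmation window (60 days by default).

Suspected-HT persons additionally get the newly-diagnosed cascade
indicators: in-window diagnosis (ICD-10 I10–I15 on/after the initial
screening), treatment start within the treatment window of diagnosis, a
post-diagnosis lipid panel (CVD risk assessment), BP control on the
latest post-diagnosis follow-up (under the cutoffs, or both readings
strictly below the initial screening), and CVD risk reduction (a later
lipid panel with total cholesterol and LDL not above the first and at
least one strictly below).

Under the default ``binary_subgroup`` scoring the headline Q is the
subgroup criterion alone and the diagnosed-cascade indicators are
reported separately; under ``strict`` scoring a diagnosed person's Q
additionally requires all four diagnosed-cascade criteria.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .bp import BPCategory, SubgroupAssignment
from .config import CriteriaConfig, StudyConfig
from .records import RecordBundle

CRITERION_BY_CATEGORY = {
    "normotension": "bp_measured",
    "pre_ht": "risk_assessed",
    "suspected_ht": "timely_confirmation",
}


@dataclasses.dataclass(frozen=True)
class QResult:
    person_id: str
    q: float
    criterion_applied: str
    details: dict


@dataclasses.dataclass(frozen=True)
class DiagnosedCascade:
    person_id: str
    diagnosed_ht: bool
    diagnosis_date: Optional[pd.Timestamp] = None
    treated_timely: bool = False
    cvd_risk_assessed: bool = False
    bp_controlled: bool = False
    cvd_risk_reduced: bool = False

    def __post_init__(self):
        if not self.diagnosed_ht and (
            self.treated_timely
            or self.cvd_risk_assessed
            or self.bp_controlled
            or self.cvd_risk_reduced
        ):
            raise ValueError("downstream flags require diagnosed_ht")
        if self.cvd_risk_reduced and not self.cvd_risk_assessed:
            raise ValueError("cvd_risk_reduced requires cvd_risk_assessed")


def compute_individual_ec(q: float, u: int, n: int) -> float:
    """Individual effective coverage EC = Q x U, defined only where N = 1."""
    if n != 1:
        raise ValueError("EC is defined only over the need population (n = 1)")
    if not 0 <= q <= 1:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if u not in (0, 1):
        raise ValueError(f"u must be 0 or 1, got {u}")
    return q * u


def _require_category(assignment: SubgroupAssignment, expected: BPCategory):
    if assignment.category != expected:
        raise ValueError(
            f"expected category {expected.value}, got {assignment.category}"
        )


def q_normotension(assignment: SubgroupAssignment) -> QResult:
    """Normotension criterion: at least one BP measurement in the year.

    Screening itself satisfies it, so Q = 1 for every screened
    normotensive person (U = 1 by construction of the assignment).
    """
    _require_category(assignment, BPCategory.NORMOTENSION)
    return QResult(assignment.person_id, 1.0, "bp_measured", {"bp_measured": True})


def q_pre_ht(
    assignment: SubgroupAssignment,
    services: pd.DataFrame,
    study: StudyConfig,
    criteria: CriteriaConfig | None = None,
) -> QResult:
    """Pre-HT criterion: HT & CVD risk assessment after the initial screening."""
    _require_category(assignment, BPCategory.PRE_HT)
    rows = services[
        services["person_id"].isin([assignment.person_id])
        & services["service_code"].isin(["ht_cvd_risk_assessment"])
    ]
    start, end = pd.Timestamp(study.study_year_start), pd.Timestamp(study.study_year_end)
    ok = (
        (rows["event_date"] >= start)
        & (rows["event_date"] <= end)
        & (rows["event_date"] >= assignment.initial_screening_date)
    )
    met = bool(ok.any())
    return QResult(
        assignment.person_id, float(met), "risk_assessed", {"risk_assessed": met}
    )


def q_suspected(
    assignment: SubgroupAssignment,
    screenings: pd.DataFrame,
    followups: pd.DataFrame,
    study: StudyConfig,
    criteria: CriteriaConfig,
) -> QResult:
    """Suspected-HT criterion: repeat BP within the confirmation window.

    A repeat is a later screening record or a follow-up BP event dated in
    ``(initial, initial + confirmation_window_days]`` — same-day repeats
    do not count.
    """
    _require_category(assignment, BPCategory.SUSPECTED_HT)
    pid = assignment.person_id
    dates = pd.concat(
        [
            screenings.loc[screenings["person_id"].isin([pid]), "event_date"],
            followups.loc[
                followups["person_id"].isin([pid])
                & followups["service_code"].isin(["follow_up_bp"]),
                "event_date",
            ],
        ]
    )
    delta = (dates - assignment.initial_screening_date).dt.days
    met = bool(((delta > 0) & (delta <= criteria.confirmation_window_days)).any())
    return QResult(pid, float(met), "timely_confirmation", {"timely_confirmation": met})


def diagnosed_cascade(
    assignment: SubgroupAssignment,
    diagnoses: pd.DataFrame,
    services: pd.DataFrame,
    followups: pd.DataFrame,
    study: StudyConfig,
    criteria: CriteriaConfig,
) -> DiagnosedCascade:
    """Newly-diagnosed cascade indicators for one suspected-HT person."""
    _require_category(assignment, BPCategory.SUSPECTED_HT)
    pid = assignment.person_id
    start, end = pd.Timestamp(study.study_year_start), pd.Timestamp(study.study_year_end)

    dx = diagnoses[diagnoses["person_id"].isin([pid])]
    codes = dx["icd10_code"].astype("string").str.upper()
    is_ht = codes.str.startswith(tuple(study.ht_icd10_prefixes)).fillna(False)
    dx = dx[
        is_ht.astype(bool)
        & (dx["event_date"] >= start)
        & (dx["event_date"] <= end)
        & (dx["event_date"] >= assignment.initial_screening_date)
    ]
    if dx.empty:
        return DiagnosedCascade(pid, diagnosed_ht=False)
    dx_date = dx["event_date"].min()

    treat = services[
        services["person_id"].isin([pid])
        & services["service_code"].isin(["ht_treatment_start"])
    ]
    tdelta = (treat["event_date"] - dx_date).dt.days
    treated = bool(((tdelta >= 0) & (tdelta <= criteria.treatment_window_days)).any())

    panels = services[
        services["person_id"].isin([pid])
        & services["service_code"].isin(["lipid_panel"])
    ]
    required = sorted(criteria.cvd_assessment_required_lipids)
    complete = panels[required].notna().all(axis=1) if required else pd.Series(
        True, index=panels.index
    )
    qual = panels[complete.astype(bool) & (panels["event_date"] >= dx_date)]
    assessed = not qual.empty

    controlled = False
    fu = followups[
        followups["person_id"].isin([pid])
        & followups["service_code"].isin(["follow_up_bp"])
        & (followups["event_date"] > dx_date)
    ]
    if not fu.empty:
        latest = fu.sort_values("event_date", kind="stable").iloc[-1]
        under = (
            latest["sbp"] < criteria.bp_control_sbp_max
            and latest["dbp"] < criteria.bp_control_dbp_max
        )
        below_initial = (
            latest["sbp"] < assignment.sbp and latest["dbp"] < assignment.dbp
        )
        controlled = bool(under or below_initial)

    reduced = False
    if assessed:
        comp = qual[qual["total_chol"].notna() & qual["ldl"].notna()]
        if not comp.empty:
            comp = comp.sort_values("event_date", kind="stable")
            first = comp.iloc[0]
            later = comp[comp["event_date"] > first["event_date"]]
            not_worse = (later["total_chol"] <= first["total_chol"]) & (
                later["ldl"] <= first["ldl"]
            )
            better = (later["total_chol"] < first["total_chol"]) | (
                later["ldl"] < first["ldl"]
            )
            reduced = bool((not_worse & better).any())

    return DiagnosedCascade(
        pid,
        diagnosed_ht=True,
        diagnosis_date=dx_date,
        treated_timely=treated,
        cvd_risk_assessed=assessed,
        bp_controlled=controlled,
        cvd_risk_reduced=reduced,
    )


# ---------------------------------------------------------------------------
# vectorized evaluation used by the pipeline


def _met_ids(frame: pd.DataFrame, ok: pd.Series) -> set:
    return set(frame.loc[ok.astype(bool), "person_id"])


def evaluate_effectiveness(
    bundle: RecordBundle,
    subgroups: pd.DataFrame,
    study: StudyConfig,
    criteria: CriteriaConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every screened person and build the diagnosed cascade table.

    Returns ``(q_table, cascade_table)``: one row per screened person with
    ``person_id``, ``category``, ``criterion_applied``, ``criterion_met``,
    ``q``; and one row per suspected-HT person with the diagnosed-cascade
    flags.  Implements the same rules as the per-person functions above,
    as vectorized joins.
    """
    start, end = pd.Timestamp(study.study_year_start), pd.Timestamp(study.study_year_end)
    sub = subgroups[subgroups["screened"]].copy()

    # pre-HT: risk assessment on/after the initial screening, in window
    pre = sub[sub["category"] == "pre_ht"]
    ra = bundle.services[
        bundle.services["service_code"].isin(["ht_cvd_risk_assessment"])
        & (bundle.services["event_date"] >= start)
        & (bundle.services["event_date"] <= end)
    ][["person_id", "event_date"]]
    j = pre[["person_id", "initial_screening_date"]].merge(ra, on="person_id")
    pre_met = _met_ids(j, j["event_date"] >= j["initial_screening_date"])

    # suspected: repeat BP in (initial, initial + window]
    susp = sub[sub["category"] == "suspected_ht"]
    repeats = pd.concat(
        [
            bundle.screenings[["person_id", "event_date"]],
            bundle.followups.loc[
                bundle.followups["service_code"].isin(["follow_up_bp"]),
                ["person_id", "event_date"],
            ],
        ],
        ignore_index=True,
    )
    j = susp[["person_id", "initial_screening_date"]].merge(repeats, on="person_id")
    delta = (j["event_date"] - j["initial_screening_date"]).dt.days
    confirmed = _met_ids(j, (delta > 0) & (delta <= criteria.confirmation_window_days))

    # diagnosis: HT ICD-10 in window, on/after initial screening; earliest wins
    dxs = bundle.diagnoses
    codes = dxs["icd10_code"].astype("string").str.upper()
    is_ht = codes.str.startswith(tuple(study.ht_icd10_prefixes)).fillna(False).astype(bool)
    dxs = dxs.loc[is_ht & (dxs["event_date"] >= start) & (dxs["event_date"] <= end)]
    j = susp[["person_id", "initial_screening_date"]].merge(
        dxs[["person_id", "event_date"]], on="person_id"
    )
    j = j[j["event_date"] >= j["initial_screening_date"]]
    dx_date = j.groupby("person_id")["event_date"].min()

    diag = susp[["person_id", "sbp", "dbp"]].merge(
        dx_date.rename("diagnosis_date"), left_on="person_id", right_index=True,
        how="left",
    )
    diag["diagnosed_ht"] = diag["diagnosis_date"].notna()
    dd = diag[diag["diagnosed_ht"]].copy()

    # timely treatment within the window from diagnosis
    tr = bundle.services.loc[
        bundle.services["service_code"].isin(["ht_treatment_start"]),
        ["person_id", "event_date"],
    ]
    j = dd[["person_id", "diagnosis_date"]].merge(tr, on="person_id")
    tdelta = (j["event_date"] - j["diagnosis_date"]).dt.days
    treated = _met_ids(j, (tdelta >= 0) & (tdelta <= criteria.treatment_window_days))

    # lipid-panel CVD risk assessment on/after diagnosis
    required = sorted(criteria.cvd_assessment_required_lipids)
    panels = bundle.services[
        bundle.services["service_code"].isin(["lipid_panel"])
    ].copy()
    if required:
        panels = panels[panels[required].notna().all(axis=1)]
    jp = dd[["person_id", "diagnosis_date"]].merge(
        panels[["person_id", "event_date", "total_chol", "ldl"]], on="person_id"
    )
    jp = jp[jp["event_date"] >= jp["diagnosis_date"]]
    assessed = set(jp["person_id"])

    # BP control on the latest post-diagnosis follow-up
    fu = bundle.followups.loc[
        bundle.followups["service_code"].isin(["follow_up_bp"]),
        ["person_id", "event_date", "sbp", "dbp"],
    ].rename(columns={"sbp": "fu_sbp", "dbp": "fu_dbp"})
    j = dd[["person_id", "diagnosis_date", "sbp", "dbp"]].merge(fu, on="person_id")
    j = j[j["event_date"] > j["diagnosis_date"]]
    j["_row"] = np.arange(len(j))
    j = j.sort_values(["person_id", "event_date", "_row"], kind="stable")
    latest = j.drop_duplicates("person_id", keep="last")
    under = (latest["fu_sbp"] < criteria.bp_control_sbp_max) & (
        latest["fu_dbp"] < criteria.bp_control_dbp_max
    )
    below = (latest["fu_sbp"] < latest["sbp"]) & (latest["fu_dbp"] < latest["dbp"])
    controlled = _met_ids(latest, (under | below).fillna(False))

    # risk reduction: a later lipid panel improving on the first
    jc = jp[jp["total_chol"].notna() & jp["ldl"].notna()].copy()
    jc["_row"] = np.arange(len(jc))
    jc = jc.sort_values(["person_id", "event_date", "_row"], kind="stable")
    firsts = jc.drop_duplicates("person_id", keep="first")[
        ["person_id", "event_date", "total_chol", "ldl"]
    ].rename(
        columns={"event_date": "d0", "total_chol": "chol0", "ldl": "ldl0"}
    )
    jr = jc.merge(firsts, on="person_id")
    jr = jr[jr["event_date"] > jr["d0"]]
    not_worse = (jr["total_chol"] <= jr["chol0"]) & (jr["ldl"] <= jr["ldl0"])
    better = (jr["total_chol"] < jr["chol0"]) | (jr["ldl"] < jr["ldl0"])
    reduced = _met_ids(jr, (not_worse & better).fillna(False)) & assessed

    cascade = diag[["person_id", "diagnosed_ht", "diagnosis_date"]].copy()
    dmask = cascade["diagnosed_ht"].to_numpy()
    cascade["treated_timely"] = cascade["person_id"].isin(treated) & dmask
    cascade["cvd_risk_assessed"] = cascade["person_id"].isin(assessed) & dmask
    cascade["bp_controlled"] = cascade["person_id"].isin(controlled) & dmask
    cascade["cvd_risk_reduced"] = cascade["person_id"].isin(reduced) & dmask

    # assemble the Q table
    q = sub[["person_id", "category"]].copy()
    q["criterion_applied"] = q["category"].map(CRITERION_BY_CATEGORY)
    met = np.full(len(q), False)
    catv = q["category"].to_numpy()
    met[catv == "normotension"] = True
    met[catv == "pre_ht"] = q.loc[catv == "pre_ht", "person_id"].isin(pre_met)
    met[catv == "suspected_ht"] = q.loc[
        catv == "suspected_ht", "person_id"
    ].isin(confirmed)
    q["criterion_met"] = met
    q_met = met.copy()
    if criteria.q_scoring == "strict":
        all_four = cascade[
            cascade[
                ["treated_timely", "cvd_risk_assessed", "bp_controlled",
                 "cvd_risk_reduced"]
            ].all(axis=1)
        ]["person_id"]
        diagnosed_ids = set(cascade.loc[cascade["diagnosed_ht"], "person_id"])
        strict_ok = ~q["person_id"].isin(diagnosed_ids) | q["person_id"].isin(
            set(all_four)
        )
        q_met = q_met & ((catv != "suspected_ht") | strict_ok.to_numpy())
    q["q"] = q_met.astype(float)
    return q.reset_index(drop=True), cascade.reset_index(drop=True)
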