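"""Per-subgroup effectiveness criteria and the diagnosed cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htcover import (
    BPCategory,
    CriteriaConfig,
    GenerationMode,
    StudyConfig,
    SubgroupAssignment,
    assess,
    compute_individual_ec,
    diagnosed_cascade,
    generate_cohort,
    paper2013_preset,
    q_normotension,
    q_pre_ht,
    q_suspected,
)
from htcover.records import make_table


def _assignment(category, date="2013-03-01", sbp=None, dbp=None):
    defaults = {"normotension": (110, 70), "pre_ht": (130, 85),
                "suspected_ht": (160, 100)}
    s, d = defaults[category]
    return SubgroupAssignment(
        person_id="X",
        screened=True,
        initial_screening_date=pd.Timestamp(date),
        sbp=sbp or s,
        dbp=dbp or d,
        category=BPCategory(category),
    )


def _services(rows):
    return make_table("services", pd.DataFrame(rows) if rows else None)


def _screenings(rows):
    return make_table("screenings", pd.DataFrame(rows) if rows else None)


def _followups(rows):
    return make_table("followups", pd.DataFrame(rows) if rows else None)


def test_q_normotension_is_always_one():
    res = q_normotension(_assignment("normotension"))
    assert res.q == 1.0 and res.criterion_applied == "bp_measured"
    with pytest.raises(ValueError):
        q_normotension(_assignment("pre_ht"))


@pytest.mark.parametrize(
    "event_date,expected",
    [("2013-03-11", 1.0),  # 10 days after screening
     ("2013-03-01", 1.0),  # same day counts (on/after)
     ("2013-02-20", 0.0),  # before the screening
     (None, 0.0)],
)
def test_q_pre_ht_requires_post_screening_assessment(event_date, expected, study):
    rows = (
        [dict(person_id="X", event_date=event_date,
              service_code="ht_cvd_risk_assessment")]
        if event_date
        else []
    )
    res = q_pre_ht(_assignment("pre_ht"), _services(rows), study)
    assert res.q == expected


@pytest.mark.parametrize("offset,expected", [(59, 1.0), (60, 1.0), (61, 0.0),
                                             (1, 1.0), (0, 0.0)])
def test_q_suspected_confirmation_window(offset, expected, study, criteria):
    date = pd.Timestamp("2013-03-01") + pd.Timedelta(days=offset)
    scr = _screenings([dict(person_id="X", event_date=str(date.date()),
                            sbp=150, dbp=95)])
    res = q_suspected(_assignment("suspected_ht"), scr, _followups([]),
                      study, criteria)
    assert res.q == expected


def test_follow_up_bp_event_counts_as_repeat(study, criteria):
    fu = _followups([dict(person_id="X", event_date="2013-04-15",
                          service_code="follow_up_bp", sbp=135, dbp=85)])
    res = q_suspected(_assignment("suspected_ht"), _screenings([]), fu,
                      study, criteria)
    assert res.q == 1.0


@settings(max_examples=100, derandomize=True)
@given(offset=st.integers(0, 200), w1=st.integers(1, 120), w2=st.integers(1, 120))
def test_widening_the_window_never_lowers_q(offset, w1, w2):
    """Confirmation is monotone in the window length."""
    study = StudyConfig()
    lo, hi = sorted((w1, w2))
    date = pd.Timestamp("2013-03-01") + pd.Timedelta(days=offset)
    scr = _screenings([dict(person_id="X", event_date=str(date.date()),
                            sbp=150, dbp=95)])
    qs = [
        q_suspected(
            _assignment("suspected_ht"), scr, _followups([]), study,
            CriteriaConfig(confirmation_window_days=w),
        ).q
        for w in (lo, hi)
    ]
    assert qs[0] <= qs[1]


def _dx_rows(day="2013-03-31"):
    return [dict(person_id="X", event_date=day, icd10_code="I10")]


def _diag(services=(), followups=(), diagnoses=None, criteria=None, study=None,
          assignment=None):
    return diagnosed_cascade(
        assignment or _assignment("suspected_ht"),
        make_table("diagnoses", pd.DataFrame(diagnoses if diagnoses is not None
                                             else _dx_rows())),
        _services(list(services)),
        _followups(list(followups)),
        study or StudyConfig(),
        criteria or CriteriaConfig(),
    )


def test_treatment_within_six_months_of_diagnosis():
    # diagnosis 30 days after screening, treatment 70 days later
    res = _diag(services=[dict(person_id="X", event_date="2013-06-09",
                               service_code="ht_treatment_start")])
    assert res.diagnosed_ht and res.treated_timely
    # exactly at the window edge (183 days after 2013-03-31)
    res = _diag(services=[dict(person_id="X", event_date="2013-09-30",
                               service_code="ht_treatment_start")])
    assert res.treated_timely
    res = _diag(services=[dict(person_id="X", event_date="2013-10-01",
                               service_code="ht_treatment_start")])
    assert not res.treated_timely


def test_pre_screening_diagnosis_does_not_count():
    res = _diag(diagnoses=[dict(person_id="X", event_date="2013-01-15",
                                icd10_code="I10")])
    assert not res.diagnosed_ht
    assert not (res.treated_timely or res.cvd_risk_assessed or res.bp_controlled
                or res.cvd_risk_reduced)


def test_no_lipid_panel_means_no_assessment_nor_reduction():
    res = _diag()
    assert res.diagnosed_ht
    assert not res.cvd_risk_assessed and not res.cvd_risk_reduced


def _panel(day, chol, ldl, hdl=45):
    return dict(person_id="X", event_date=day, service_code="lipid_panel",
                total_chol=chol, ldl=ldl, hdl=hdl)


def test_risk_reduction_requires_improved_second_panel():
    first = _panel("2013-04-10", 240, 160)
    assert _diag(services=[first]).cvd_risk_assessed
    assert not _diag(services=[first]).cvd_risk_reduced
    improved = _panel("2013-05-10", 230, 160)
    res = _diag(services=[first, improved])
    assert res.cvd_risk_reduced
    flat = _panel("2013-05-10", 240, 160)
    assert not _diag(services=[first, flat]).cvd_risk_reduced
    worse_one = _panel("2013-05-10", 230, 170)  # LDL rose: not_worse fails
    assert not _diag(services=[first, worse_one]).cvd_risk_reduced


def test_pre_diagnosis_panel_is_ignored():
    res = _diag(services=[_panel("2013-02-01", 240, 160)])
    assert not res.cvd_risk_assessed


def _fu(day, sbp, dbp):
    return dict(person_id="X", event_date=day, service_code="follow_up_bp",
                sbp=sbp, dbp=dbp)


def test_bp_control_on_latest_follow_up():
    # under control by the absolute cutoffs
    assert _diag(followups=[_fu("2013-06-01", 130, 80)]).bp_controlled
    # not under cutoffs but below the initial 160/100 reading
    assert _diag(followups=[_fu("2013-06-01", 150, 95)]).bp_controlled
    # equal to the initial level: neither criterion holds
    assert not _diag(followups=[_fu("2013-06-01", 160, 100)]).bp_controlled
    # only the latest follow-up counts
    res = _diag(followups=[_fu("2013-06-01", 120, 70), _fu("2013-08-01", 180, 110)])
    assert not res.bp_controlled
    res = _diag(followups=[_fu("2013-06-01", 180, 110), _fu("2013-08-01", 120, 70)])
    assert res.bp_controlled
    # follow-up before the diagnosis date does not count
    assert not _diag(followups=[_fu("2013-02-01", 120, 70)]).bp_controlled


def test_individual_ec_identities():
    assert compute_individual_ec(1.0, 1, 1) == 1.0
    assert compute_individual_ec(0.5, 1, 1) == 0.5
    assert compute_individual_ec(1.0, 0, 1) == 0.0
    with pytest.raises(ValueError):
        compute_individual_ec(1.0, 1, 0)


def test_vectorized_and_scalar_paths_agree(study, criteria):
    """The pipeline's joined evaluation equals the per-person functions."""
    bundle = generate_cohort(
        paper2013_preset(1500), GenerationMode(mode="stochastic", seed=11)
    )
    run = assess(bundle, study, criteria)
    res = run.results.set_index("person_id")
    sub = res[res["screened"].eq(True)]
    checked = {"pre_ht": 0, "suspected_ht": 0}
    scr = bundle.screenings
    for pid, row in sub.iterrows():
        if row["category"] == "normotension":
            continue
        mine = scr[scr["person_id"] == pid].sort_values(
            ["event_date", "sbp", "dbp"], ascending=[True, False, False]
        ).iloc[0]
        assignment = SubgroupAssignment(
            person_id=pid,
            screened=True,
            initial_screening_date=row["initial_screening_date"],
            sbp=int(mine["sbp"]),
            dbp=int(mine["dbp"]),
            category=BPCategory(row["category"]),
        )
        if row["category"] == "pre_ht":
            expect = q_pre_ht(assignment, bundle.services, study).q
            assert row["q"] == expect, pid
            checked["pre_ht"] += 1
        else:
            expect = q_suspected(assignment, bundle.screenings, bundle.followups,
                                 study, criteria).q
            assert row["q"] == expect, pid
            casc = diagnosed_cascade(assignment, bundle.diagnoses, bundle.services,
                                     bundle.followups, study, criteria)
            for flag in ("diagnosed_ht", "treated_timely", "cvd_risk_assessed",
                         "bp_controlled", "cvd_risk_reduced"):
                assert bool(row[flag]) == getattr(casc, flag), (pid, flag)
            checked["suspected_ht"] += 1
    assert checked["pre_ht"] > 50 and checked["suspected_ht"] > 20


def test_strict_scoring_requires_full_cascade_for_diagnosed(study):
    bundle = generate_cohort(
        paper2013_preset(4000), GenerationMode(mode="exact_quota", seed=2)
    )
    binary = assess(bundle, study, CriteriaConfig(q_scoring="binary_subgroup"))
    strict = assess(bundle, study, CriteriaConfig(q_scoring="strict"))
    assert strict.national_ec <= binary.national_ec
    rb = binary.results.set_index("person_id")
    rs = strict.results.set_index("person_id")
    diagnosed = rs[rs["diagnosed_ht"]]
    full = diagnosed[["treated_timely", "cvd_risk_assessed", "bp_controlled",
                      "cvd_risk_reduced"]].all(axis=1)
    assert (diagnosed.loc[~full, "q"] == 0.0).all()
    not_diag = rs[rs["screened"].eq(True) & ~rs["diagnosed_ht"]]
    pd.testing.assert_series_equal(
        rs.loc[not_diag.index, "q"], rb.loc[not_diag.index, "q"]
    )
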