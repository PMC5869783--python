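"""Cascade tallies, province summaries, and national statistics."""

import json

import numpy as np
import pandas as pd
import pytest

from htcover import (
    GenerationMode,
    GeneratorPreset,
    assess,
    build_cascade,
    generate_cohort,
    national_summary,
    paper2013_preset,
    province_varying_preset,
    summarize_provinces,
)


def _results_frame(rows):
    base = dict(
        person_id="", sex="male", province_code=1, age=40, age_band="35-59",
        eligible=True, exclusion_reason=None, screened=False,
        initial_screening_date=None, category=None, q=np.nan,
        pre_ht_risk_assessed=False, suspected_confirmed=False,
        diagnosed_ht=False, diagnosis_date=None, treated_timely=False,
        cvd_risk_assessed=False, bp_controlled=False, cvd_risk_reduced=False,
    )
    recs = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec.update(row, person_id=f"R{i:03d}")
        recs.append(rec)
    frame = pd.DataFrame(recs)
    u = frame["screened"].eq(True).astype(float)
    frame["ec"] = (frame["q"].fillna(0.0) * u).where(frame["eligible"].eq(True))
    return frame


def test_hand_fixture_counts_match_manual_tallies():
    rows = (
        [dict(eligible=False, exclusion_reason="under_age")] * 2
        + [dict(screened=False)] * 4
        + [dict(screened=True, category="normotension", q=1.0)] * 6
        + [dict(screened=True, category="pre_ht", q=1.0,
                pre_ht_risk_assessed=True)] * 3
        + [dict(screened=True, category="pre_ht", q=0.0)] * 2
        + [dict(screened=True, category="suspected_ht", q=1.0,
                suspected_confirmed=True, diagnosed_ht=True, treated_timely=True,
                cvd_risk_assessed=True, bp_controlled=True)] * 1
        + [dict(screened=True, category="suspected_ht", q=0.0)] * 2
    )
    cascade = build_cascade(_results_frame(rows)).check()
    d = cascade.to_dict()
    assert d["eligible"] == {"numerator": 18, "denominator": 20, "percent": 90.0}
    assert d["screened"]["numerator"] == 14
    assert d["normotension"]["numerator"] == 6
    assert d["pre_ht"] == {"numerator": 5, "denominator": 14,
                           "percent": pytest.approx(100 * 5 / 14)}
    assert d["pre_ht_risk_assessed"]["numerator"] == 3
    assert d["suspected_confirmed_60d"] == {
        "numerator": 1, "denominator": 3, "percent": pytest.approx(100 / 3)
    }
    assert d["diagnosed"]["numerator"] == 1
    assert d["treated_timely"] == {"numerator": 1, "denominator": 1, "percent": 100.0}
    assert d["cvd_risk_reduced"]["numerator"] == 0


def test_empty_denominators_are_undefined_not_zero():
    preset = paper2013_preset(500).model_copy(
        update={"subgroup_shares": (0.8, 0.2, 0.0)}
    )
    run = assess(generate_cohort(preset, GenerationMode(mode="exact_quota", seed=1)))
    assert run.cascade.proportion("diagnosed") is None
    assert run.cascade.proportion("treated_timely") is None
    frame = run.cascade.to_frame()
    assert (frame.loc[frame["node"] == "diagnosed", "percent"] == "").all()
    # undefined percentages serialize as null, not 0
    assert json.dumps(run.cascade.to_dict())


def test_province_identities_and_example():
    rows = []
    # province 1: coverage 0.6, effectiveness 1.0 -> ec 0.6
    rows += [dict(province_code=1, screened=True, category="normotension", q=1.0)] * 6
    rows += [dict(province_code=1)] * 4
    # province 2: coverage 0.4, effectiveness 0.5 -> ec 0.2
    rows += [dict(province_code=2, screened=True, category="pre_ht", q=1.0,
                  pre_ht_risk_assessed=True)] * 2
    rows += [dict(province_code=2, screened=True, category="pre_ht", q=0.0)] * 2
    rows += [dict(province_code=2)] * 6
    prov = summarize_provinces(_results_frame(rows)).set_index("province_code")
    assert prov.loc[1, "coverage"] == pytest.approx(0.6)
    assert prov.loc[1, "ec"] == pytest.approx(0.6)
    assert prov.loc[2, "ec"] == pytest.approx(0.2)
    assert prov["ec"].to_numpy() == pytest.approx(
        (prov["coverage"] * prov["effectiveness"]).to_numpy()
    )


def test_zero_eligible_province_is_omitted_with_warning():
    rows = [dict(province_code=1, screened=True, category="normotension", q=1.0),
            dict(province_code=2, eligible=False, exclusion_reason="under_age")]
    with pytest.warns(UserWarning, match="zero eligible"):
        prov = summarize_provinces(_results_frame(rows))
    assert prov["province_code"].tolist() == [1]


def test_degenerate_province_set_has_undefined_correlation():
    rows = []
    for code in (1, 2, 3):
        rows += [dict(province_code=code, screened=True, category="normotension",
                      q=1.0)] * 2
        rows += [dict(province_code=code)] * 2
    frame = _results_frame(rows)
    nat = national_summary(summarize_provinces(frame), frame)
    assert nat.pearson_r is None and nat.p_value is None
    assert nat.provincial_min_ec <= nat.provincial_mean_ec <= nat.provincial_max_ec


def test_exactly_linear_provinces_have_unit_correlation():
    rows = []
    specs = {1: (10, 8, 4), 2: (10, 6, 3), 3: (10, 4, 2), 4: (10, 2, 1)}
    for code, (n, screened, q1) in specs.items():
        rows += [dict(province_code=code, screened=True, category="pre_ht", q=1.0,
                      pre_ht_risk_assessed=True)] * q1
        rows += [dict(province_code=code, screened=True, category="pre_ht",
                      q=0.0)] * (screened - q1)
        rows += [dict(province_code=code)] * (n - screened)
    frame = _results_frame(rows)
    prov = summarize_provinces(frame)
    # ec = coverage * 0.5 per construction
    assert prov["ec"].to_numpy() == pytest.approx(0.5 * prov["coverage"].to_numpy())
    nat = national_summary(prov, frame)
    assert nat.pearson_r == pytest.approx(1.0)
    assert nat.gap_mean == pytest.approx((prov["coverage"] - prov["ec"]).mean())


def test_pooled_numerators_equal_sum_of_provincial_numerators():
    bundle = generate_cohort(
        province_varying_preset(20_000, n_provinces=10),
        GenerationMode(mode="stochastic", seed=3),
    )
    run = assess(bundle)
    pooled = run.cascade.to_dict()
    sums = {name: 0.0 for name in pooled}
    for code in run.provinces["province_code"]:
        mask = run.results["province_code"] == code
        sub = build_cascade(run.results, stratum=mask).to_dict()
        for name in sums:
            sums[name] += sub[name]["numerator"]
    for name, node in pooled.items():
        assert node["numerator"] == sums[name], name


def test_weighted_and_unweighted_means_both_reported():
    bundle = generate_cohort(
        province_varying_preset(15_000, n_provinces=8),
        GenerationMode(mode="stochastic", seed=9),
    )
    run = assess(bundle)
    nat = run.national
    w = run.provinces["n_eligible"] / run.provinces["n_eligible"].sum()
    assert nat.provincial_weighted_mean_ec == pytest.approx(
        float((run.provinces["ec"] * w).sum())
    )
    assert nat.provincial_mean_ec == pytest.approx(float(run.provinces["ec"].mean()))


def test_pearson_matches_textbook_formula_on_varying_provinces():
    """Package correlation vs an independent implementation of
    r = cov(x, y) / (sd_x * sd_y) on the same provincial summaries."""
    bundle = generate_cohort(
        province_varying_preset(200_000),
        GenerationMode(mode="stochastic", seed=1),
    )
    run = assess(bundle)
    x = run.provinces["coverage"].to_numpy()
    y = run.provinces["ec"].to_numpy()
    r_oracle = float(
        ((x - x.mean()) * (y - y.mean())).sum()
        / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    )
    assert run.national.pearson_r == pytest.approx(r_oracle, abs=0.02)
    assert run.national.p_value < 0.001
    # heterogeneous provinces correlate strongly, as coverage dominates EC
    assert run.national.pearson_r > 0.95
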