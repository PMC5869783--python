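"""Synthetic cohort generation with a known care-cascade structure.

The real administrative database behind this kind of analysis is
restricted, so every pipeline stage is exercised on generated record
bundles whose cascade structure is known exactly.  A
:class:`GeneratorPreset` fixes the branch probabilities of the cascade
(screening coverage, BP subgroup shares, and the per-subgroup service
probabilities); :func:`generate_cohort` emits a full six-table
:class:`~htcover.records.RecordBundle` realizing them and
:func:`ground_truth` returns the cascade the pipeline is expected to
recover.

Two modes: ``exact_quota`` assigns deterministic branch counts
(round-half-up of parent x p, with largest-remainder correction for the
three-way subgroup split) so recovery is exact to the count; in
``stochastic`` mode every branch is an independent per-person Bernoulli
draw, optionally modulated by per-province logit-scale effects.

Generation is seeded and byte-reproducible.  Screened persons get a raw
(SBP, DBP) reading drawn inside their assigned category's region, so the
pipeline must re-derive the category from values.  For every service
criterion, unmet cases are split ~50/50 between "no event" and an
out-of-window (or otherwise non-qualifying) event, so both failure paths
of each criterion occur.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .aggregate import CascadeTable, make_cascade
from .config import CriteriaConfig, StudyConfig
from .records import RecordBundle, make_table

# Per-province covariate model: name -> (mean, sd) across provinces,
# resembling published provincial statistics for Thailand 2013.
DEFAULT_COVARIATE_MODEL: dict[str, tuple[float, float]] = {
    "midyear_population_million": (0.8, 0.47),
    "pct_urban": (34.4, 15.03),
    "gpp_100k_per_capita": (1.4, 1.40),
    "pop_1000_per_primary_care_unit": (6.1, 2.74),
    "pop_1000_per_physician": (4.2, 1.41),
}

_Prob = Field(ge=0.0, le=1.0)


class GeneratorPreset(BaseModel):
    """Branch probabilities and demographic structure of a synthetic cohort."""

    n_persons: int = Field(gt=0)
    n_provinces: int = Field(default=76, gt=0)
    study_year: int = 2013
    p_screened: float = _Prob
    subgroup_shares: tuple[float, float, float]
    p_pre_assessed: float = _Prob
    p_susp_confirmed: float = _Prob
    p_susp_diagnosed: float = _Prob
    p_dx_treated: float = _Prob
    p_dx_assessed: float = _Prob
    p_dx_controlled: float = _Prob
    p_dx_risk_reduced: float = _Prob
    province_effects: Optional[tuple[float, ...]] = None
    age_bands: tuple[tuple[int, int], ...] = ((15, 34), (35, 59), (60, 84))
    age_band_shares: tuple[float, ...] = (0.38, 0.42, 0.20)
    p_female: float = Field(default=0.5, ge=0.0, le=1.0)
    covariate_model: dict[str, tuple[float, float]] = dict(DEFAULT_COVARIATE_MODEL)

    @model_validator(mode="after")
    def _consistent(self):
        if abs(sum(self.subgroup_shares) - 1.0) > 1e-9:
            raise ValueError("subgroup_shares must sum to 1")
        if any(s < 0 for s in self.subgroup_shares):
            raise ValueError("subgroup_shares must be non-negative")
        if abs(sum(self.age_band_shares) - 1.0) > 1e-9:
            raise ValueError("age_band_shares must sum to 1")
        if len(self.age_band_shares) != len(self.age_bands):
            raise ValueError("age_band_shares must match age_bands")
        if self.province_effects is not None and len(
            self.province_effects
        ) != self.n_provinces:
            raise ValueError("province_effects must have one entry per province")
        return self


class GenerationMode(BaseModel):
    mode: Literal["stochastic", "exact_quota"] = "exact_quota"
    seed: int


def paper2013_preset(n_persons: int = 1_000_000) -> GeneratorPreset:
    """The replication preset: the 2013 national HT-screening cascade.

    Coverage 54.6%; subgroup shares 65.1 / 28.9 / 6.0%; pre-HT risk
    assessment 82.6%; 60-day confirmation 38.0%; diagnosis 9.2% of
    suspected; then 36.5 / 21.8 / 50.8 / 0.7% of the diagnosed for
    timely treatment, CVD assessment, BP control, and risk reduction.
    """
    return GeneratorPreset(
        n_persons=n_persons,
        n_provinces=76,
        p_screened=0.546,
        subgroup_shares=(0.651, 0.289, 0.060),
        p_pre_assessed=0.826,
        p_susp_confirmed=0.380,
        p_susp_diagnosed=0.092,
        p_dx_treated=0.365,
        p_dx_assessed=0.218,
        p_dx_controlled=0.508,
        p_dx_risk_reduced=0.007,
    )


def province_varying_preset(
    n_persons: int = 200_000,
    n_provinces: int = 76,
    effect_sd: float = 0.9,
    effect_seed: int = 20130076,
) -> GeneratorPreset:
    """Replication preset plus heterogeneous provinces.

    Per-province logit-scale effects drawn once from N(0, effect_sd)
    with a fixed seed, producing a wide provincial coverage spread for
    qualitative cross-province testing.
    """
    rng = np.random.default_rng(effect_seed)
    effects = tuple(float(x) for x in rng.normal(0.0, effect_sd, n_provinces))
    base = paper2013_preset(n_persons)
    return base.model_copy(
        update={"n_provinces": n_provinces, "province_effects": effects}
    )


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def allocate_counts(total: int, shares) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` into ``shares``."""
    shares = np.asarray(shares, dtype=float)
    raw = total * shares
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _shift_p(p: float, effects: np.ndarray) -> np.ndarray:
    """Apply logit-scale province effects to a probability, clamped to [0,1]."""
    if p <= 0.0 or p >= 1.0:
        return np.full_like(effects, p, dtype=float)
    logit = math.log(p / (1.0 - p))
    return 1.0 / (1.0 + np.exp(-(logit + effects)))


def _expected_p(p: float, preset: GeneratorPreset) -> float:
    """Population-average probability under uniform province assignment."""
    if preset.province_effects is None:
        return p
    return float(np.mean(_shift_p(p, np.asarray(preset.province_effects))))


# quality parameters modulated by province effects (stochastic mode);
# subgroup shares and diagnosis incidence stay global
_PROVINCE_MODULATED = {
    "p_screened",
    "p_pre_assessed",
    "p_susp_confirmed",
    "p_dx_treated",
    "p_dx_assessed",
    "p_dx_controlled",
}


class _Sampler:
    """Branch-membership sampling shared by the two modes."""

    def __init__(self, preset: GeneratorPreset, mode: GenerationMode, rng, provinces):
        self.preset = preset
        self.quota = mode.mode == "exact_quota"
        self.rng = rng
        self.provinces = provinces  # 1-based codes per person

    def pick(self, parent_idx: np.ndarray, p: float, param: str) -> np.ndarray:
        """Subset of ``parent_idx`` assigned to the branch."""
        if len(parent_idx) == 0:
            return parent_idx
        if self.quota:
            k = round_half_up(len(parent_idx) * p)
            perm = self.rng.permutation(parent_idx)
            return np.sort(perm[:k])
        effects = self.preset.province_effects
        if effects is not None and param in _PROVINCE_MODULATED:
            pp = _shift_p(p, np.asarray(effects)[self.provinces[parent_idx] - 1])
        else:
            pp = p
        draws = self.rng.random(len(parent_idx))
        return parent_idx[draws < pp]


def generate_cohort(
    preset: GeneratorPreset,
    mode: GenerationMode,
    criteria: CriteriaConfig | None = None,
    study: StudyConfig | None = None,
) -> RecordBundle:
    """Generate a record bundle realizing the preset's cascade."""
    criteria = criteria or CriteriaConfig()
    if study is None:
        study = StudyConfig(
            study_year_start=pd.Timestamp(preset.study_year, 1, 1).date(),
            study_year_end=pd.Timestamp(preset.study_year, 12, 31).date(),
        )
    rng = np.random.default_rng(mode.seed)
    n = preset.n_persons
    start = pd.Timestamp(study.study_year_start)
    year_len = (pd.Timestamp(study.study_year_end) - start).days  # last valid offset
    W = criteria.confirmation_window_days
    T = criteria.treatment_window_days

    # --- persons -----------------------------------------------------------
    ids = np.char.add("P", np.char.zfill(np.arange(n).astype(str), 7))
    sex = np.where(rng.random(n) < preset.p_female, "female", "male")
    band = rng.choice(len(preset.age_bands), size=n, p=preset.age_band_shares)
    lo = np.array([b[0] for b in preset.age_bands])[band]
    hi = np.array([b[1] for b in preset.age_bands])[band]
    age = rng.integers(lo, hi + 1)
    anniversary = pd.to_datetime(
        {"year": start.year - age, "month": start.month, "day": start.day}
    )
    birth = anniversary - pd.to_timedelta(rng.integers(0, 365, n), unit="D")
    provinces = rng.integers(1, preset.n_provinces + 1, size=n)

    # --- cascade membership ------------------------------------------------
    s = _Sampler(preset, mode, rng, provinces)
    idx = np.arange(n)
    screened = s.pick(idx, preset.p_screened, "p_screened")
    if s.quota:
        counts = allocate_counts(len(screened), preset.subgroup_shares)
        perm = rng.permutation(screened)
        norm_idx = np.sort(perm[: counts[0]])
        pre_idx = np.sort(perm[counts[0] : counts[0] + counts[1]])
        susp_idx = np.sort(perm[counts[0] + counts[1] :])
    else:
        u = rng.random(len(screened))
        edges = np.cumsum(preset.subgroup_shares)
        norm_idx = screened[u < edges[0]]
        pre_idx = screened[(u >= edges[0]) & (u < edges[1])]
        susp_idx = screened[u >= edges[1]]

    pre_assessed = s.pick(pre_idx, preset.p_pre_assessed, "p_pre_assessed")
    confirmed = s.pick(susp_idx, preset.p_susp_confirmed, "p_susp_confirmed")
    diagnosed = s.pick(susp_idx, preset.p_susp_diagnosed, "p_susp_diagnosed")
    treated = s.pick(diagnosed, preset.p_dx_treated, "p_dx_treated")
    assessed = s.pick(diagnosed, preset.p_dx_assessed, "p_dx_assessed")
    controlled = s.pick(diagnosed, preset.p_dx_controlled, "p_dx_controlled")
    # risk reduction is defined through two lipid panels, so it can only
    # occur within the assessed subset; the marginal among diagnosed is
    # preserved (capped by p_dx_assessed when infeasible)
    if s.quota:
        k = min(round_half_up(len(diagnosed) * preset.p_dx_risk_reduced), len(assessed))
        reduced = np.sort(rng.permutation(assessed)[:k])
    else:
        p_cond = (
            min(1.0, preset.p_dx_risk_reduced / preset.p_dx_assessed)
            if preset.p_dx_assessed > 0
            else 0.0
        )
        reduced = assessed[rng.random(len(assessed)) < p_cond]

    in_conf = np.zeros(n, bool)
    in_conf[confirmed] = True
    in_assessed = np.zeros(n, bool)
    in_assessed[assessed] = True

    # --- event dates and values -------------------------------------------
    # initial screenings in the first nine months so confirmation and
    # treatment windows can close inside the study year
    screen_day = np.full(n, -1)
    # leave room for the confirmation window plus the follow-up offset
    max_screen = max(0, min(272, year_len - W - 31))
    screen_day[screened] = rng.integers(0, max_screen + 1, len(screened))

    sbp = np.zeros(n, int)
    dbp = np.zeros(n, int)

    def draw_region(index, kind):
        m = len(index)
        if m == 0:
            return
        alt = rng.random(m) < 0.2  # readings crossing only the DBP threshold
        if kind == "norm":
            sbp[index] = rng.integers(90, 120, m)
            dbp[index] = rng.integers(50, 80, m)
        elif kind == "pre":
            sbp[index] = np.where(alt, rng.integers(100, 120, m), rng.integers(120, 140, m))
            dbp[index] = np.where(alt, rng.integers(80, 90, m), rng.integers(70, 90, m))
        else:  # suspected, capped at 220/120
            sbp[index] = np.where(alt, rng.integers(100, 140, m), rng.integers(140, 221, m))
            dbp[index] = np.where(alt, rng.integers(90, 100, m), rng.integers(60, 121, m))

    draw_region(norm_idx, "norm")
    draw_region(pre_idx, "pre")
    draw_region(susp_idx, "susp")

    def coin(index):
        return rng.random(len(index)) < 0.5

    # pre-HT risk assessment: met -> day in [screen, screen+30]; unmet ->
    # half no event, half an event strictly before the screening date
    ra_idx = [pre_assessed]
    ra_day = [screen_day[pre_assessed] + rng.integers(0, 31, len(pre_assessed))]
    unmet = np.setdiff1d(pre_idx, pre_assessed, assume_unique=True)
    early = unmet[coin(unmet)]
    day = screen_day[early] - rng.integers(1, 31, len(early))
    keep = day >= 0
    ra_idx.append(early[keep])
    ra_day.append(day[keep])

    # suspected confirmation: a second screening record; met -> within
    # (0, W]; unmet -> half none, half in [W+1, W+90] (dropped past year end)
    rep_idx = [confirmed]
    rep_day = [screen_day[confirmed] + rng.integers(1, W + 1, len(confirmed))]
    unmet = np.setdiff1d(susp_idx, confirmed, assume_unique=True)
    late = unmet[coin(unmet)]
    day = screen_day[late] + W + rng.integers(1, 91, len(late))
    keep = day <= year_len
    rep_idx.append(late[keep])
    rep_day.append(day[keep])

    # diagnosis: met -> [screen+1, screen+30]; non-diagnosed -> half get a
    # pre-screening (but in-year) diagnosis that must not count
    dx_day = np.full(n, -1)
    dx_day[diagnosed] = screen_day[diagnosed] + rng.integers(1, 31, len(diagnosed))
    dxe_idx = [diagnosed]
    dxe_day = [dx_day[diagnosed]]
    unmet = np.setdiff1d(susp_idx, diagnosed, assume_unique=True)
    early = unmet[coin(unmet)]
    day = screen_day[early] - rng.integers(1, 31, len(early))
    keep = day >= 0
    dxe_idx.append(early[keep])
    dxe_day.append(day[keep])

    prefixes = np.array(["I10", "I11", "I12", "I13", "I15"])

    # treatment start: met -> within [1, min(T, room)] of diagnosis;
    # unmet -> half none, half at [T+1, T+90] when it fits in the year
    tr_idx = [treated]
    room = year_len - dx_day[treated]
    tr_day = [dx_day[treated] + rng.integers(1, np.minimum(T, room) + 1)]
    unmet = np.setdiff1d(diagnosed, treated, assume_unique=True)
    late = unmet[coin(unmet)]
    day = dx_day[late] + T + rng.integers(1, 91, len(late))
    keep = day <= year_len
    tr_idx.append(late[keep])
    tr_day.append(day[keep])

    # lipid panels: assessed -> first panel in [dx+1, dx+20]; unassessed ->
    # half a pre-diagnosis panel; reduced -> improved second panel; other
    # assessed -> half an unimproved (identical-lipids) second panel
    p1_day = np.full(n, -1)
    p1_day[assessed] = dx_day[assessed] + rng.integers(1, 21, len(assessed))
    chol1 = np.zeros(n, int)
    ldl1 = np.zeros(n, int)
    hdl1 = np.zeros(n, int)
    chol1[assessed] = rng.integers(200, 261, len(assessed))
    ldl1[assessed] = rng.integers(130, 181, len(assessed))
    hdl1[assessed] = rng.integers(35, 61, len(assessed))

    lp_idx = [assessed]
    lp_day = [p1_day[assessed]]
    lp_chol = [chol1[assessed]]
    lp_ldl = [ldl1[assessed]]
    lp_hdl = [hdl1[assessed]]

    unmet = np.setdiff1d(diagnosed, assessed, assume_unique=True)
    early = unmet[coin(unmet)]
    day = dx_day[early] - rng.integers(1, 31, len(early))
    keep = day >= 0
    early = early[keep]
    lp_idx.append(early)
    lp_day.append(day[keep])
    lp_chol.append(rng.integers(200, 261, len(early)))
    lp_ldl.append(rng.integers(130, 181, len(early)))
    lp_hdl.append(rng.integers(35, 61, len(early)))

    lp_idx.append(reduced)
    lp_day.append(p1_day[reduced] + rng.integers(1, 21, len(reduced)))
    lp_chol.append(chol1[reduced] - rng.integers(1, 31, len(reduced)))
    lp_ldl.append(ldl1[reduced] - rng.integers(1, 31, len(reduced)))
    lp_hdl.append(rng.integers(35, 61, len(reduced)))

    unmet = np.setdiff1d(assessed, reduced, assume_unique=True)
    flat = unmet[coin(unmet)]
    lp_idx.append(flat)
    lp_day.append(p1_day[flat] + rng.integers(1, 21, len(flat)))
    lp_chol.append(chol1[flat])
    lp_ldl.append(ldl1[flat])
    lp_hdl.append(rng.integers(35, 61, len(flat)))

    # BP-control follow-up: controlled -> normotensive reading; uncontrolled
    # -> half none, half a reading equal to the initial screening (neither
    # under control nor below the initial level).  For diagnosed persons
    # *not* flagged confirmed the follow-up is pushed past the confirmation
    # window so it cannot flip the confirmation criterion.
    fu_candidates = np.concatenate(
        [controlled, np.setdiff1d(diagnosed, controlled, assume_unique=True)]
    )
    has_event = np.concatenate(
        [
            np.ones(len(controlled), bool),
            coin(np.setdiff1d(diagnosed, controlled, assume_unique=True)),
        ]
    )
    fu_idx = np.sort(fu_candidates[has_event])
    base = np.where(
        in_conf[fu_idx],
        dx_day[fu_idx] + 1,
        np.maximum(dx_day[fu_idx] + 1, screen_day[fu_idx] + W + 1),
    )
    fu_day = base + rng.integers(0, 31, len(fu_idx))
    keep = fu_day <= year_len
    fu_idx, fu_day = fu_idx[keep], fu_day[keep]
    in_ctrl = np.zeros(n, bool)
    in_ctrl[controlled] = True
    good = in_ctrl[fu_idx]
    fu_sbp = np.where(good, rng.integers(90, 120, len(fu_idx)), sbp[fu_idx])
    fu_dbp = np.where(good, rng.integers(50, 80, len(fu_idx)), dbp[fu_idx])

    # --- assemble tables ----------------------------------------------------
    def dates(day_array):
        return start + pd.to_timedelta(day_array, unit="D")

    persons = make_table(
        "persons",
        {
            "person_id": ids,
            "birth_date": birth,
            "sex": sex,
            "province_code": provinces,
            "in_civil_registry": np.ones(n, bool),
        },
    )

    scr_person = np.concatenate([screened] + rep_idx)
    scr_day = np.concatenate([screen_day[screened]] + rep_day)
    rep_all = np.concatenate(rep_idx)
    rep_m = len(rep_all)
    scr_sbp = np.concatenate([sbp[screened], rng.integers(140, 221, rep_m)])
    scr_dbp = np.concatenate([dbp[screened], rng.integers(60, 121, rep_m)])
    screenings = make_table(
        "screenings",
        {
            "person_id": ids[scr_person],
            "event_date": dates(scr_day),
            "sbp": scr_sbp,
            "dbp": scr_dbp,
        },
    )

    svc_parts = []
    ra_all, ra_d = np.concatenate(ra_idx), np.concatenate(ra_day)
    svc_parts.append(
        pd.DataFrame(
            {
                "person_id": ids[ra_all],
                "event_date": dates(ra_d),
                "service_code": "ht_cvd_risk_assessment",
            }
        )
    )
    tr_all, tr_d = np.concatenate(tr_idx), np.concatenate(tr_day)
    svc_parts.append(
        pd.DataFrame(
            {
                "person_id": ids[tr_all],
                "event_date": dates(tr_d),
                "service_code": "ht_treatment_start",
            }
        )
    )
    lp_all = np.concatenate(lp_idx)
    svc_parts.append(
        pd.DataFrame(
            {
                "person_id": ids[lp_all],
                "event_date": dates(np.concatenate(lp_day)),
                "service_code": "lipid_panel",
                "total_chol": np.concatenate(lp_chol),
                "ldl": np.concatenate(lp_ldl),
                "hdl": np.concatenate(lp_hdl),
            }
        )
    )
    services = make_table("services", pd.concat(svc_parts, ignore_index=True))

    followups = make_table(
        "followups",
        {
            "person_id": ids[fu_idx],
            "event_date": dates(fu_day),
            "service_code": "follow_up_bp",
            "sbp": fu_sbp,
            "dbp": fu_dbp,
        },
    )

    dx_all = np.concatenate(dxe_idx)
    diagnoses = make_table(
        "diagnoses",
        {
            "person_id": ids[dx_all],
            "event_date": dates(np.concatenate(dxe_day)),
            "icd10_code": rng.choice(prefixes, len(dx_all)),
        },
    )

    registry = make_table("registry")
    _ = in_assessed
    return RecordBundle(
        persons=persons,
        screenings=screenings,
        services=services,
        diagnoses=diagnoses,
        registry=registry,
        followups=followups,
    )


def ground_truth(preset: GeneratorPreset, mode: GenerationMode) -> CascadeTable:
    """The cascade the pipeline should recover from a generated cohort.

    Exact integer counts in ``exact_quota`` mode; expectations (possibly
    non-integer) in ``stochastic`` mode.
    """
    n = preset.n_persons
    if mode.mode == "exact_quota":
        n_scr = round_half_up(n * preset.p_screened)
        c = allocate_counts(n_scr, preset.subgroup_shares)
        n_norm, n_pre, n_susp = (int(x) for x in c)
        n_pre_as = round_half_up(n_pre * preset.p_pre_assessed)
        n_conf = round_half_up(n_susp * preset.p_susp_confirmed)
        n_diag = round_half_up(n_susp * preset.p_susp_diagnosed)
        n_tr = round_half_up(n_diag * preset.p_dx_treated)
        n_as = round_half_up(n_diag * preset.p_dx_assessed)
        n_ctrl = round_half_up(n_diag * preset.p_dx_controlled)
        n_red = min(round_half_up(n_diag * preset.p_dx_risk_reduced), n_as)
        return make_cascade(
            n, n, n_scr, n_norm, n_pre, n_susp,
            n_pre_as, n_conf, n_diag, n_tr, n_as, n_ctrl, n_red,
        ).check()
    # expectations; with province effects, downstream branches co-vary
    # with screening within a province, so average the per-province
    # *products* of probabilities rather than multiplying the averages
    if preset.province_effects is not None:
        eff = np.asarray(preset.province_effects)
        p_scr = _shift_p(preset.p_screened, eff)
        p_pre_as = _shift_p(preset.p_pre_assessed, eff)
        p_conf = _shift_p(preset.p_susp_confirmed, eff)
        p_tr = _shift_p(preset.p_dx_treated, eff)
        p_as = _shift_p(preset.p_dx_assessed, eff)
        p_ctrl = _shift_p(preset.p_dx_controlled, eff)
    else:
        p_scr = np.array([preset.p_screened])
        p_pre_as = np.array([preset.p_pre_assessed])
        p_conf = np.array([preset.p_susp_confirmed])
        p_tr = np.array([preset.p_dx_treated])
        p_as = np.array([preset.p_dx_assessed])
        p_ctrl = np.array([preset.p_dx_controlled])
    shares = preset.subgroup_shares
    e_scr = n * float(np.mean(p_scr))
    e_norm, e_pre, e_susp = (e_scr * s for s in shares)
    p_diag = preset.p_susp_diagnosed
    e_diag = e_susp * p_diag
    e_red_p = min(preset.p_dx_risk_reduced, preset.p_dx_assessed)
    return make_cascade(
        n, n, e_scr, e_norm, e_pre, e_susp,
        n * shares[1] * float(np.mean(p_scr * p_pre_as)),
        n * shares[2] * float(np.mean(p_scr * p_conf)),
        e_diag,
        n * shares[2] * p_diag * float(np.mean(p_scr * p_tr)),
        n * shares[2] * p_diag * float(np.mean(p_scr * p_as)),
        n * shares[2] * p_diag * float(np.mean(p_scr * p_ctrl)),
        e_diag * e_red_p,
    )


def generate_province_covariates(preset: GeneratorPreset, seed: int) -> pd.DataFrame:
    """Per-province covariate table drawn from the preset's covariate model."""
    rng = np.random.default_rng(seed)
    out = {"province_code": np.arange(1, preset.n_provinces + 1)}
    for name, (mean, sd) in preset.covariate_model.items():
        vals = rng.normal(mean, sd, preset.n_provinces)
        out[name] = np.maximum(vals, 0.01 * abs(mean) if mean else 0.0)
    return pd.DataFrame(out)
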