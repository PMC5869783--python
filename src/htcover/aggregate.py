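"""Cascade tables, province summaries, and national comparative statistics.

The care cascade is the sequence of conditional proportions from
eligibility through screening, BP subgroups, confirmation, diagnosis,
treatment, and control.  Denominators are fixed and documented: subgroup
nodes use the screened count; the confirmation and diagnosis nodes use
the suspected-HT count; the four post-diagnosis nodes all use the
diagnosed count.  An empty denominator yields an *undefined* proportion
(None), never zero.

Effective coverage per stratum is the mean of Q x U over eligible
persons; crude coverage is the mean of U; effectiveness is the mean of Q
among the screened, so with binary scoring EC = coverage x effectiveness
holds identically per stratum.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

NODE_ORDER = [
    "eligible",
    "screened",
    "normotension",
    "pre_ht",
    "suspected_ht",
    "pre_ht_risk_assessed",
    "suspected_confirmed_60d",
    "diagnosed",
    "treated_timely",
    "cvd_risk_assessed",
    "bp_controlled",
    "cvd_risk_reduced",
]


@dataclasses.dataclass(frozen=True)
class CascadeNode:
    name: str
    numerator: float
    denominator: float

    @property
    def proportion(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> Optional[float]:
        p = self.proportion
        return None if p is None else 100.0 * p


@dataclasses.dataclass
class CascadeTable:
    """Ordered (numerator, denominator) pairs for every cascade node."""

    nodes: dict[str, CascadeNode]

    def proportion(self, name: str) -> Optional[float]:
        return self.nodes[name].proportion

    def percent(self, name: str) -> Optional[float]:
        return self.nodes[name].percent

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in NODE_ORDER:
            node = self.nodes[name]
            rows.append(
                {
                    "node": name,
                    "numerator": node.numerator,
                    "denominator": node.denominator,
                    "percent": "" if node.percent is None else f"{node.percent:.1f}",
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            name: {
                "numerator": node.numerator,
                "denominator": node.denominator,
                "percent": node.percent,
            }
            for name, node in self.nodes.items()
        }

    def check(self):
        """Raise if structural invariants are violated."""
        for name, node in self.nodes.items():
            if node.numerator > node.denominator:
                raise ValueError(f"{name}: numerator exceeds denominator")
            if node.numerator < 0:
                raise ValueError(f"{name}: negative numerator")
        n = self.nodes
        total = (
            n["normotension"].numerator
            + n["pre_ht"].numerator
            + n["suspected_ht"].numerator
        )
        if not np.isclose(total, n["screened"].numerator):
            raise ValueError("subgroup counts do not sum to screened count")
        return self


def make_cascade(
    n_total,
    n_eligible,
    n_screened,
    n_norm,
    n_pre,
    n_susp,
    n_pre_assessed,
    n_confirmed,
    n_diagnosed,
    n_treated,
    n_assessed,
    n_controlled,
    n_reduced,
) -> CascadeTable:
    pairs = [
        ("eligible", n_eligible, n_total),
        ("screened", n_screened, n_eligible),
        ("normotension", n_norm, n_screened),
        ("pre_ht", n_pre, n_screened),
        ("suspected_ht", n_susp, n_screened),
        ("pre_ht_risk_assessed", n_pre_assessed, n_pre),
        ("suspected_confirmed_60d", n_confirmed, n_susp),
        ("diagnosed", n_diagnosed, n_susp),
        ("treated_timely", n_treated, n_diagnosed),
        ("cvd_risk_assessed", n_assessed, n_diagnosed),
        ("bp_controlled", n_controlled, n_diagnosed),
        ("cvd_risk_reduced", n_reduced, n_diagnosed),
    ]
    return CascadeTable({name: CascadeNode(name, num, den) for name, num, den in pairs})


def build_cascade(results: pd.DataFrame, stratum=None) -> CascadeTable:
    """Tally every cascade node over the persons passing ``stratum``.

    ``results`` is the assembled per-person frame (see
    :func:`htcover.pipeline.assemble_results`); ``stratum`` is an optional
    boolean mask aligned with it (all persons when None).
    """
    r = results if stratum is None else results.loc[np.asarray(stratum, bool)]
    elig = r["eligible"].to_numpy(bool)
    scr = r["screened"].eq(True).to_numpy(bool) & elig
    cat = r["category"].to_numpy(object)

    def flag(col):
        return r[col].eq(True).to_numpy(bool)

    susp = scr & (cat == "suspected_ht")
    return make_cascade(
        n_total=len(r),
        n_eligible=int(elig.sum()),
        n_screened=int(scr.sum()),
        n_norm=int((scr & (cat == "normotension")).sum()),
        n_pre=int((scr & (cat == "pre_ht")).sum()),
        n_susp=int(susp.sum()),
        n_pre_assessed=int((scr & (cat == "pre_ht") & flag("pre_ht_risk_assessed")).sum()),
        n_confirmed=int((susp & flag("suspected_confirmed")).sum()),
        n_diagnosed=int((susp & flag("diagnosed_ht")).sum()),
        n_treated=int((susp & flag("treated_timely")).sum()),
        n_assessed=int((susp & flag("cvd_risk_assessed")).sum()),
        n_controlled=int((susp & flag("bp_controlled")).sum()),
        n_reduced=int((susp & flag("cvd_risk_reduced")).sum()),
    )


def summarize_provinces(results: pd.DataFrame) -> pd.DataFrame:
    """Coverage, effectiveness, and EC per province.

    Provinces with zero eligible persons are omitted with a warning.
    EC = mean(Q x U) over eligible persons; effectiveness = mean(Q) among
    the screened (NaN when nobody is screened).
    """
    r = results[results["eligible"]].copy()
    r["u"] = r["screened"].eq(True).astype(float)
    r["qu"] = r["q"].fillna(0.0) * r["u"]
    all_provinces = results["province_code"].dropna().unique()
    grouped = r.groupby("province_code", observed=True)
    out = grouped.agg(
        n_eligible=("person_id", "size"),
        coverage=("u", "mean"),
        ec=("qu", "mean"),
    ).reset_index()
    eff = (
        r[r["u"] == 1.0]
        .groupby("province_code", observed=True)["q"]
        .mean()
        .rename("effectiveness")
    )
    out = out.merge(eff, on="province_code", how="left")
    empty = set(all_provinces) - set(out["province_code"])
    if empty:
        warnings.warn(
            f"provinces with zero eligible persons omitted: {sorted(empty)}",
            stacklevel=2,
        )
    out["province_code"] = out["province_code"].astype(int)
    return out[
        ["province_code", "n_eligible", "coverage", "effectiveness", "ec"]
    ].sort_values("province_code").reset_index(drop=True)


@dataclasses.dataclass
class NationalSummary:
    cascade: CascadeTable
    n_provinces: int
    provincial_mean_ec: float
    provincial_weighted_mean_ec: float
    provincial_min_ec: float
    provincial_max_ec: float
    provincial_mean_coverage: float
    gap_min: float
    gap_max: float
    gap_mean: float
    pearson_r: Optional[float]
    p_value: Optional[float]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cascade"] = self.cascade.to_dict()
        return d


def national_summary(
    province_summaries: pd.DataFrame, results: pd.DataFrame
) -> NationalSummary:
    """Pool the cascade nationally and compare provinces.

    The provincial mean EC is reported both unweighted (mean over
    provinces) and weighted by eligible population.  The coverage-EC gap
    statistics are over ``coverage - ec`` per province.  The Pearson
    correlation between provincial coverage and EC uses the two-sided
    t-approximation; with fewer than 3 provinces or zero variance it is
    reported as undefined (None), never as a number.
    """
    p = province_summaries
    cascade = build_cascade(results)
    gap = p["coverage"] - p["ec"]
    w = p["n_eligible"] / p["n_eligible"].sum()
    r_val: Optional[float] = None
    p_val: Optional[float] = None
    if len(p) >= 3 and p["coverage"].std() > 0 and p["ec"].std() > 0:
        r_val, p_val = stats.pearsonr(p["coverage"], p["ec"])
        r_val, p_val = float(r_val), float(p_val)
    return NationalSummary(
        cascade=cascade,
        n_provinces=len(p),
        provincial_mean_ec=float(p["ec"].mean()),
        provincial_weighted_mean_ec=float((p["ec"] * w).sum()),
        provincial_min_ec=float(p["ec"].min()),
        provincial_max_ec=float(p["ec"].max()),
        provincial_mean_coverage=float(p["coverage"].mean()),
        gap_min=float(gap.min()),
        gap_max=float(gap.max()),
        gap_mean=float(gap.mean()),
        pearson_r=r_val,
        p_value=p_val,
    )
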