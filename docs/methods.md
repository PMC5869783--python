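# Methods

## The measurement model

The package operationalizes the effective-coverage framework for a
hypertension screening programme. For person *i* with need (N = 1),
individual effective coverage is `EC_i = Q_i · U_i`; population EC over
any stratum is the mean of that product over its eligible members.
Because Q is binary, three identities hold exactly and are enforced by
tests: `EC ≤ coverage` per stratum, `EC = coverage × effectiveness`
(effectiveness = mean Q among the screened), and equality of EC and
coverage iff every screened member met their criterion.

**Need (N).** Eligible = completed age ≥ `min_age_years` (default 15) at
a reference date (default: the study-window start), province in the
included set (default codes 1–76), present in the civil registry, and no
hypertension evidence dated strictly before the study window. HT
evidence is a registry entry with condition `hypertension` or a
diagnosis whose ICD-10 code starts with I10–I15. A diagnosis *during*
the study year does not exclude — such a person remains in the target
group and feeds the newly-diagnosed cascade. Completed-years age is the
standard administrative convention; "15 and older" means
`completed_years ≥ 15`, so a person whose 15th birthday falls exactly on
the reference date is eligible. The default study window is the calendar
year 2013; a fiscal-year window is a configuration change, not a code
change. Exclusion reasons are reported one per person with a fixed
priority order (missing birth date, under age, excluded province, not
registered, prior diagnosis); the priority affects only the reason
label, never the eligibility bit.

**Utilization (U) and subgroups.** U = 1 iff at least one screening
record falls inside the study window. The *initial screening* is the
earliest in-window record; same-day ties break by higher SBP, then
higher DBP, then input row order, making the assignment invariant to row
permutation. Follow-up BP service events never count as the initial
screening, which keeps screening and confirmation distinguishable.
Subgroup cutoffs (mmHg): normotension SBP < 120 and DBP < 80; pre-HT SBP
120–139 and/or DBP 80–89; suspected HT SBP ≥ 140 and/or DBP ≥ 90. The
"and/or" is implemented as precedence (suspected whenever either upper
threshold is crossed, else pre-HT whenever either lower one is), which
partitions the whole physiologic grid (SBP 50–300, DBP 30–200, DBP <
SBP) into exactly three classes; an exhaustive grid scan in the tests
confirms it.

**Quality (Q).** Per-subgroup binary criteria: normotension — the
screening itself (Q ≡ 1 once screened); pre-HT — an HT & CVD
risk-assessment service inside the study window on/after the initial
screening date (it is a post-screening intervention in the pathway);
suspected HT — a repeat BP measurement (later screening record or
follow-up BP event) in `(0, 60]` days after the initial screening. The
window is exclusive of day 0 — a same-day repeat is not a confirmation
visit — and inclusive of day 60; 60 days is used rather than "2 months"
because the day count is the sharper of the two statements of the rule.
Widening the window is monotone: it can only add confirmations.

**Newly-diagnosed cascade.** Among suspected-HT persons: diagnosed iff
an I10–I15 diagnosis is dated in-window and on/after the initial
screening (the earliest such date is the diagnosis date); treated timely
iff a treatment-start event falls within 183 days (≈ 6 months) *of the
diagnosis date* — treatment follows diagnosis in the care pathway, and
the window is configurable; CVD-risk assessed iff a lipid panel with all
required analytes (total cholesterol, LDL, HDL by default) is dated
on/after diagnosis; BP controlled iff the latest follow-up BP after
diagnosis is under the cutoffs (SBP < 140 and DBP < 90, exclusive) *or*
both readings are strictly below the initial screening values; CVD risk
reduced iff a lipid panel later than the first post-diagnosis panel has
total cholesterol and LDL not above it with at least one strictly below.
These four indicators are reported with the diagnosed count as their
denominator but are **not** folded into the headline Q: with
per-subgroup binary scoring the cascade implies a national EC of
0.546 × (0.651 + 0.289·0.826 + 0.060·0.380) ≈ 0.498, consistent with the
provincial-average EC the cascade is calibrated to, whereas folding the
diagnosed criteria in cannot be. A `strict` scoring mode (diagnosed
persons additionally need all four indicators for Q = 1) is available
behind the `q_scoring` configuration key.

**Aggregation.** Cascade denominators are fixed: subgroup nodes over the
screened; the pre-HT service node over the pre-HT count; confirmation
and diagnosis over the suspected count; the four post-diagnosis nodes
over the diagnosed count. An empty denominator yields an undefined
proportion (null in reports), never zero. Provincial summaries report
coverage, effectiveness, and EC per province (provinces with zero
eligible persons are omitted with a warning); the national summary
reports the pooled cascade, the provincial mean EC both unweighted and
weighted by eligible population (the two means differ only under
provincial heterogeneity, so both are always emitted), coverage–EC gap
statistics, and the Pearson correlation between provincial coverage and
EC with a two-sided t-approximation p-value (scipy). With fewer than
three provinces or zero variance the correlation is reported as
undefined rather than a number. Report files round percentages to one
decimal; full precision is kept internally and in `national.json`.

## The synthetic cohort generator

The generator emulates the structure, not the content, of a national
outpatient screening database: six delimited-text tables (persons,
screenings, services, diagnoses, registry, follow-ups) with ISO dates
and day-granular comparisons. Branch probabilities come from a preset;
`paper2013` encodes the published 2013 cascade (coverage 0.546, subgroup
shares 0.651/0.289/0.060, then 0.826, 0.380, 0.092, 0.365, 0.218, 0.508,
0.007 down the pathway) with a demographic structure of ~38% aged 15–34,
balanced sexes, and uniform assignment over 76 provinces.

*Exact-quota mode* computes each branch count as round-half-up of
parent × p, with largest-remainder apportionment for the three-way
subgroup split so children always sum to their parent; membership within
a parent is a seeded random subset. *Stochastic mode* draws each branch
per person, with optional per-province logit-scale effects (the
`province_varying` preset draws them once from N(0, 0.9)) applied to the
screening and service-quality probabilities — not to the subgroup shares
(they must sum to one) nor to diagnosis incidence (epidemiology, not
service quality).

Realization choices, all made so that every criterion is exercised on
both its success and failure paths and so that the pipeline must re-derive
everything from raw values:

- BP readings are drawn uniformly on integer grids inside the assigned
  category's region (suspected capped at 220/120; ~20% of pre-HT and
  suspected readings cross only the DBP threshold), so classification
  must use the actual cutoff logic.
- Initial screenings fall in the first nine months of the year so the
  confirmation and treatment windows can close in-year. In-window
  offsets are uniform on `[1, window]`; each unmet criterion is split
  ~50/50 between *no event* and a *non-qualifying event* (too late, or
  before the screening/diagnosis, or with unimproved values), dropped
  when it cannot fit inside the year.
- Confirmation repeats are emitted as second screening records;
  follow-up BP events are reserved for the BP-control indicator. For
  diagnosed persons not assigned a confirmation, the follow-up is dated
  strictly after `screening + confirmation window`, so it can never flip
  the confirmation criterion — this keeps all marginals independently
  recoverable.
- Branches are sampled independently of each other, except that CVD risk
  reduction is sampled within the CVD-assessed subset (it is defined by
  comparing two lipid panels, so the implication `reduced ⇒ assessed` is
  structural); its marginal among the diagnosed is preserved, capped by
  the assessment probability when a preset makes it infeasible.
- Half of the non-diagnosed suspected persons receive an in-year HT
  diagnosis dated *before* their screening, exercising the rule that
  only on/after-screening diagnoses enter the cascade.

`ground_truth(preset, mode)` returns the cascade the pipeline must
recover: exact counts in quota mode, expectations in stochastic mode
(with province effects, downstream expectations average per-province
*products* of probabilities, since screening and service quality co-vary
within a province). The core generator contract — full pipeline output
equals ground truth exactly in quota mode — is tested on the replication
preset and on random presets.

What the generator does **not** emulate: age/sex gradients in BP
category, within-year migration, measurement error, correlated service
seeking, Bangkok's separate information system, or the raw 21-file
layout of the real source. Passing recovery tests therefore demonstrates
that the pipeline computes the cascade correctly from records with this
schema — not that real administrative data are this clean; on real data
the permissive reader's drop counters and the validation report are the
first thing to inspect.

## Numerical and I/O choices

- Dates are calendar dates; all window arithmetic is in whole days.
- Integer columns use nullable integers so optional measurements
  round-trip CSV cleanly; writers are deterministic (identical bundles
  serialize byte-identically), and `read(write(b)) == b` field-wise.
- Strict reading aborts on the first invariant violation; permissive
  reading drops offending rows and counts them per invariant. Orphan
  events (person absent from the persons table) are violations, never
  silent joins.
- Quota rounding: round-half-up for two-way branches; largest-remainder
  (ties to the lower index) for the subgroup split. At n = 10^6 the
  recovered percentages differ from the preset by at most one rounding
  unit on the smallest denominator (~0.05 percentage points).
- Seeds: one integer seed drives the whole generation through a single
  PCG64 generator; run manifests echo the full configuration so a run
  can be reproduced bit-identically from the manifest alone.

## Problem sizes

The replication run uses n = 1,000,000 persons (a scale at which quota
rounding is far below reporting precision and which a laptop handles in
seconds); stochastic-recovery checks use 20 seeds at n = 100,000, where
3 binomial standard errors on the smallest node denominators are still
well below the preset spacing; the randomized invariant suite uses 100
presets at n = 400 across 3–7 provinces.

## Known limitations

- Q is binary; the framework admits graded quality weights, which would
  require only a different Q table but has no calibration target here.
- Multiple same-day initial screenings are resolved by the documented
  tie-break, not averaged.
- The pre-HT risk-assessment criterion accepts the service any time
  on/after the screening within the study year; no upper window is
  imposed.
- "Treatment within 6 months" is counted from the diagnosis date; if a
  user's convention counts from the screening date, set
  `treatment_window_days` accordingly and filter on the screening date
  externally.
- Province of record is fixed for the study year.
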