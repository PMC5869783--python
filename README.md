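# htcover

Effective coverage of hypertension (HT) screening, measured as a care
cascade over individual-level administrative health records.

Crude service coverage — the share of the target population that got at
least one blood-pressure measurement in a year — overstates what a
screening programme delivers: a screen that is never followed up confirms
nothing and prevents nothing. The effective-coverage framework scores,
for each person *i* in the need population,

```
EC_i = Q_i · U_i | N_i = 1
```

where **N** marks the screening target group (age ≥ 15 completed years,
resident in an included province, registered, no HT diagnosis before the
study year), **U** marks utilization (≥ 1 BP screening inside the study
year), and **Q** is a binary effectiveness criterion for the BP subgroup
of the *initial* (earliest in-window) screening:

| subgroup (initial SBP/DBP, mmHg)          | Q = 1 when the person received |
| ----------------------------------------- | ------------------------------ |
| normotension (SBP < 120 and DBP < 80)     | the BP measurement itself      |
| pre-HT (SBP 120–139 and/or DBP 80–89)     | an HT & CVD risk assessment on/after the screening |
| suspected HT (SBP ≥ 140 and/or DBP ≥ 90)  | a repeat BP measurement within 60 days of the screening |

Suspected-HT persons are additionally traced through the newly-diagnosed
cascade — in-window ICD-10 I10–I15 diagnosis, treatment start within 183
days of diagnosis, post-diagnosis lipid panel (CVD risk assessment), BP
control on the latest follow-up, and CVD risk reduction (an improved
later lipid panel). These indicators are reported per cascade node;
population EC is the mean of Q·U over the eligible population, emitted
pooled, per province, and as a provincial (weighted and unweighted) mean,
together with coverage–EC gap statistics and the Pearson correlation
between provincial coverage and EC.

Because the source administrative database (Thailand's NHSO outpatient
dataset, 2013) is restricted, the package includes a seeded synthetic
cohort generator that emits the same six-table record bundle (persons,
screenings, services, diagnoses, HT registry, follow-ups) with a known
cascade structure, in an *exact-quota* mode (deterministic branch counts,
so pipeline recovery is exact) and a *stochastic* mode (per-person
Bernoulli draws, optionally with per-province effects). The
`paper2013` preset encodes the published 2013 national cascade.

The package is for health-systems and epidemiology researchers who want
to compute effective coverage of screening programmes from record-level
data, or to stress-test such pipelines against cohorts with known truth.

## Worked example

```python
from htcover import GenerationMode, assess, generate_cohort, paper2013_preset

bundle = generate_cohort(paper2013_preset(n_persons=50_000),
                         GenerationMode(mode="exact_quota", seed=7))
result = assess(bundle)
print(result.cascade.to_frame().to_string(index=False))
print(f"national pooled EC: {100 * result.national_ec:.2f}%")
```

prints

```
                   node  numerator  denominator percent
               eligible      50000        50000   100.0
               screened      27300        50000    54.6
           normotension      17772        27300    65.1
                 pre_ht       7890        27300    28.9
           suspected_ht       1638        27300     6.0
   pre_ht_risk_assessed       6517         7890    82.6
suspected_confirmed_60d        622         1638    38.0
              diagnosed        151         1638     9.2
         treated_timely         55          151    36.4
      cvd_risk_assessed         33          151    21.9
          bp_controlled         77          151    51.0
       cvd_risk_reduced          1          151     0.7
national pooled EC: 49.82%
```

Each row is a cascade node: `numerator / denominator` with the
documented denominator (screened for the three subgroups, the subgroup
for its service criterion, the diagnosed count for the four
post-diagnosis nodes). The pipeline recovered these percentages from raw
records — dates, SBP/DBP values and ICD-10 codes — not from the preset;
the residual differences at the bottom nodes are quota rounding on small
counts. EC (49.82%) sits below crude coverage (54.6%) because a fifth of
the pre-HT group and most suspected-HT persons did not receive their
subgroup's follow-on service.

The `examples/` directory holds one short script per capability:
generation and validation, assessment, provincial variation and the
coverage–EC correlation, and the reference-cascade replication. A thin
CLI wraps the same pipeline:

```sh
htcover generate --preset paper2013 --mode exact_quota --seed 9 --n 100000 --out cohort/
htcover assess --in cohort/ --out report/        # cascade.tsv, provinces.tsv, national.json
htcover replicate-paper --n 1000000              # side-by-side recovery table
```

`htcover assess --config settings.yaml` accepts a YAML file with `study`
and `criteria` sections whose keys match the `StudyConfig` /
`CriteriaConfig` field names (study window, age minimum, included
provinces, ICD-10 prefixes; confirmation/treatment windows, BP-control
cutoffs, Q scoring).

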