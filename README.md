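# sepscreen

Prevalence and dichotomy analysis of the two bedside sepsis screens used in
intensive care — **qSOFA** (sepsis-3) and **SIRS** (sepsis-2) — over
long-format ICU chart events, for clinical data scientists and informatics
researchers studying sepsis screening criteria.

## The problem

ICU charting produces one timestamped record per (admission, parameter,
time).  Both screens flag possible sepsis when **at least two** of their
criteria are met *simultaneously*:

| Screen | Criterion | Cutoff (canonical units) |
|---|---|---|
| qSOFA | high respiratory rate | RR ≥ 22 breaths/min |
| qSOFA | altered mental status | GCS ≤ 13 |
| qSOFA | hypotension | SABP ≤ 100 mmHg |
| SIRS | abnormal temperature | BT > 100.4 °F or < 96.8 °F |
| SIRS | tachypnea | RR > 20 breaths/min |
| SIRS | tachycardia | HR > 90 beats/min |
| SIRS | abnormal WBC | WBC > 12 or < 4 (×10³/mm³) |

Note the boundary conventions: qSOFA cutoffs are inclusive, SIRS cutoffs
strict.  A *scenario* is the exact subset of criteria met at one aligned
chart time; with n criteria and a ≥2 rule there are 2ⁿ − n − 1
sepsis-positive scenarios (4 for qSOFA, 11 for SIRS) plus "no sepsis".

The package computes, for each screen and for two phases (every record of
the stay; only each admission's first observations):

* per-criterion prevalence (fraction of observations meeting each cutoff),
* scenario prevalence over aligned observations (chart times where *all*
  parameters of the screen were recorded),
* summary statistics and kernel-density curves per parameter,
* pairwise **absolute Pearson correlation** |r| with an effect-size verdict
  (negligible < 0.1 ≤ weak < 0.3 ≤ moderate < 0.5 ≤ collinear) — small |r|
  throughout indicates the parameters are non-collinear ("dichotomous") and
  can serve jointly as predictors.

Because real ICU databases of this shape are access-controlled, a
**Gaussian-copula synthetic cohort generator** reproduces the data's
structure — per-parameter charting cadence, realistic marginals, weak
pairwise correlation, injected implausible outliers, per-admission mortality
labels — so the entire pipeline is testable and demonstrable offline.

## Worked example

```sh
sepscreen simulate --seed 7 --n-admissions 40 --outlier-rate 0.01 --out cohort.csv
sepscreen screen --input cohort.csv --out out/
sepscreen report --report out/report.json --top 3
```

prints

```
simulate: seed=7 admissions=40 events=7906 outliers_injected=74 mortality_rate=0.2000 -> cohort.csv
screen: read=7906 excluded=74 kept=7832 -> out/report.json
  qSOFA/entire_trajectory: events=4904 aligned=547
  ...
== qSOFA / entire_trajectory ==
  high_respiratory_rate      44.22%  (961/2173)
  altered_mental_status      86.30%  (485/562)
  hypotension                24.16%  (524/2169)
  top scenarios (of 547 aligned):
    no_sepsis                                                      50.64%
    altered_mental_status+high_respiratory_rate                    27.97%
    altered_mental_status+hypotension                              13.89%
```

Reading this: all 74 injected implausible values were excluded by the
plausibility filter; 547 chart times carried all three qSOFA parameters at
once; the most prevalent sepsis-positive scenario in this synthetic cohort
is the altered-mental-status + high-respiratory-rate pair (27.97% of aligned
observations); per-criterion denominators differ because each parameter is
charted on its own cadence.  `out/report.json` holds the full four-way
analysis (both screens × both phases) including summary statistics, the
correlation report and exported density-curve CSVs, and validates against
the schema in `sepscreen.pipeline.REPORT_SCHEMA`.

The same analyses are available as library calls (`read_chart_events`,
`filter_plausible`, `align`, `evaluate`, `scenario_prevalence`,
`pairwise_dichotomy`, `kde`, `generate_cohort`, `run_pipeline`, …); see the
module docstrings.

## Scope

The package implements only the two bedside screens named above: no full
SOFA scoring, no septic-shock operationalization (vasopressors/lactate), no
severe-sepsis staging, and no database connectors — input is the documented
chart-event CSV dialect.  See `docs/methods.md` for the model and design
decisions.
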