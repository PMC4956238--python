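# bpscreen

Predictive-validity analysis for back-pain screening questionnaires.

About 10–15% of people with non-specific back pain develop persistent
symptoms, and psychosocial risk factors ("yellow flags") predict that
transition. Two screening instruments used in German care settings — the
German translation of the **Örebro Musculoskeletal Pain Screening
Questionnaire** (ÖMPSQ, 21 scored items, linear total 4–212) and the
**Heidelberger Kurzfragebogen Rückenschmerz** (HKF-R 10, regression-weighted
score with five risk categories) — aim to catch patients at risk early.
`bpscreen` implements the full validation pipeline for such instruments,
for biostatisticians and outcomes researchers: questionnaire scoring with
reverse-coded items, checkbox-missing work items and capped mean
substitution; dichotomization of six-month outcomes (pain, function, sick
leave); and a diagnostic-validity engine producing ROC coordinate tables,
nonparametric AUC with Hanley–McNeil standard errors, Youden-optimal
cut-offs, likelihood ratios, predictive values with Bayesian prevalence
re-adjustment, and test-efficiency classifications. A calibrated
synthetic-cohort generator stands in for patient data, so every stage runs
and is testable end to end.

The statistical core, for a marker X (questionnaire total) against a binary
six-month state D (not recovered):

* AUC = P(X_D > X_N) + ½·P(X_D = X_N) (tie-aware Mann–Whitney), SE by
  Hanley–McNeil, z-test against 0.5, CI = AUC ± 1.96·SE.
* Per cut-off c (positive iff X ≥ c): Se, Sp, J = Se + Sp − 1,
  PLR = Se/(1−Sp), NLR = (1−Se)/Sp, PPV, NPV, accuracy; the optimal c
  maximizes J.
* Prevalence adjustment via the odds form of Bayes' theorem:
  post-odds(+) = π/(1−π) · PLR, PPV = post-odds/(1+post-odds), and
  NPV = 1/(1 + π/(1−π)·NLR).

## Worked example

Simulate a study-sized cohort (265 baselines, ~50% six-month return,
outcome prevalences 50/37/52/70%), then run the full analysis:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_validity_analysis.py
```

(The CLI equivalents are `bpscreen simulate --seed 1 --n 265 --out cohort/`
followed by `bpscreen validate cohort/baseline.csv cohort/followup.csv
--prevalence 0.10 --out study/`.) The report ends with the Youden-optimal
validity rows:

```
        outcome  cutoff  sensitivity  specificity  youden_j   plr   nlr   ppv   npv  adj_ppv  adj_npv plr_band
     ompsq_pain  107.55        0.776        0.716     0.492 2.736 0.313 0.703 0.787    0.233    0.966 moderate
ompsq_sickleave  113.50        0.683        0.696     0.379 2.244 0.456 0.571 0.787    0.200    0.952 moderate
 ompsq_function  109.50        0.738        0.750     0.488 2.951 0.350 0.738 0.750    0.247    0.963 moderate
       hkf_pain   16.45        0.717        0.559     0.276 1.626 0.506 0.815 0.422    0.153    0.947      low
```

Read: for the pain outcome, the cut-off maximizing Youden's J classifies
77.6% of non-recovered and 71.6% of recovered patients correctly; a
positive screen multiplies the odds of chronicity by 2.7 ("moderate" test
efficiency). Within the enriched sample the PPV is 0.70, but re-adjusted
to the 10% population prevalence (`adj_ppv`) it collapses to 0.23 — the
study's central caveat about clinical utility, reproduced here in
simulation. The stand-alone calculator does the same adjustment for any
likelihood ratios:

```bash
$ bpscreen adjust-pv --plr 19 --nlr 0.0526 --prevalence 0.1
prevalence=0.1 PPV=0.679 NPV=0.994
```

The numbered scripts under `analysis/` run the same flow as a narrative
(simulate → score → validity tables → published-table recomputation →
parameter recovery), writing their tables under `results/`.

Note: the HKF-R 10's published regression coefficients are not
redistributed; the packaged weight file is synthetic (see
`src/bpscreen/data/hkf_weights_synthetic.yaml`) and exists to exercise the
scoring machinery. Supply the genuine table via `--weight-spec` for real
use.

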