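# Methods

`bpscreen` implements the predictive-validity analysis used to evaluate two
back-pain screening questionnaires in German primary/secondary care: the
German translation of the Örebro Musculoskeletal Pain Screening
Questionnaire (ÖMPSQ) and the Heidelberger Kurzfragebogen Rückenschmerz
(HKF-R 10). Both instruments screen for psychosocial risk factors
("yellow flags") that predict the transition from acute to chronic
non-specific back pain. The analysis treats each baseline total score as a
continuous diagnostic marker for a dichotomized six-month outcome and
quantifies its validity with ROC methodology.

## Questionnaire scoring

**ÖMPSQ (German translation).** 21 of 25 items are scored (IDs 5–25; four
sociodemographic items are excluded). Most items are 0–10 ratings; three
use a 1–10 scale, and the pain-sites item (six categories) is counted
twice. Eight items (12, 16, 17, 21–25) are reverse-coded (`10 − raw`) so
that larger transformed values always mean higher risk; the linear total
spans 4–212 and maps to risk bands low (< 91), medium (91–106) and high
(> 106), compared on the real-valued total without prior rounding. Three
work items (8, 16, 17) carry a "not working" checkbox: a ticked box without
a scale mark is a missing value, while an existing scale mark always
overrides the box (discarding it would force an avoidable substitution).
Processing order is fixed: checkbox resolution → reverse-coding/doubling →
mean substitution. Up to 3 missing items (≈14% of 21) are replaced by the
arithmetic mean of the answered *transformed* values — substitution after
the scoring rules keeps the imputed value on the risk scale, and it
preserves the record's transformed mean exactly. More than 3 missing items
invalidates the record.

The entire item table (scales, inversion, doubling, checkbox flags, band
edges, substitution cap) is a YAML config, so the original Swedish 4–210
variant or an alternate numbering is a data change. The identity of the two
non-pain-sites 1–10 items is not fixed by the instrument description we
relied on; the default table assigns items 6 and 7 and documents this as a
placeholder.

**HKF-R 10.** 27 items; item 5 (last-week pain VAS, 0–100) is recorded but
never scored. The score is regression-based: an intercept plus a weighted
sum of positive and negative "sum products" over the 26 scored items, with
five categories at the fixed boundaries ≤ −2.5 (low), ≤ 8 (probably low),
< 28 (no prediction), < 37 (probably high), ≥ 37 (high). Missing values are
not allowed — incomplete records are invalid, never imputed. The published
regression coefficients are not reproduced here: the packaged weight file
is **synthetic**, exists only to exercise the scoring machinery and
category logic, and must be replaced for substantive use. The weight spec
accepts item-level or group-level (subscale-sum) terms because either
weighting convention is representable.

## Outcome dichotomization (6 months)

ROC analysis needs binary states; "recovered" is test-negative,
"not recovered" is test-positive ("diseased" in the code):

| outcome | key variable | rule |
|---|---|---|
| ÖMPSQ pain | item 10 × item 11 (0–100) | recovered iff product < 17 |
| ÖMPSQ function | sum of raw items 21–25 (0–50) | recovered iff sum ≥ 45 |
| ÖMPSQ sick leave | self-reported days | recovered iff 0 days |
| HKF pain | HKF item 5 VAS (0–100) | recovered iff VAS < 30 |

The function outcome uses *raw* item values (10 = best function), unlike
baseline scoring which reverse-codes these items — the ≥ 45 rule requires
high sums to mean recovery. Sick leave additionally keeps the descriptive
trichotomy 0 / 1–30 / > 30 days, consistent with the dichotomy by
construction. A record missing an outcome's inputs has no label for that
outcome and drops from that outcome's sub-sample only; sub-samples are the
intersection of valid baseline scores with present labels.

## Diagnostic validity

Test-positive means `score ≥ cutoff` (configurable to strict `>`).
Candidate cut-offs are midpoints between consecutive distinct observed
scores plus one sentinel below the minimum and one above the maximum (the
convention of classic statistics-package coordinate tables), giving n+1
coordinate points for n distinct scores. Per cut-off:
sensitivity, specificity, Youden's J = sens + spec − 1,
PLR = sens/(1 − spec), NLR = (1 − sens)/spec, PPV, NPV, accuracy and
prevalence. Division by zero yields `inf` for likelihood ratios and an
undefined flag (NaN) for predictive values rather than an exception. The
Youden-optimal cut-off maximizes J, ties broken toward the smaller cut-off.

AUC is the tie-aware Mann–Whitney probability
P(X_D > X_N) + ½·P(X_D = X_N), computed from midranks; its SE uses the
Hanley–McNeil distribution-free formula with Q1 = A/(2 − A),
Q2 = 2A²/(1 + A); the null test against 0.5 is an asymptotic normal z-test
(p = 1 when SE = 0 at A = 0.5), and the 95% CI is A ± 1.96·SE clipped to
[0, 1]. An exact Mann–Whitney p-value is exposed for small samples as a
cross-check of the asymptotic test.

Predictive values are re-adjusted to an arbitrary population prevalence
through the odds form of Bayes' theorem: with pre-odds = π/(1 − π),
PPV = pre-odds·PLR / (1 + pre-odds·PLR) and NPV = 1/(1 + pre-odds·NLR).
At the sample prevalence this reproduces the confusion matrix's own
PPV/NPV to machine precision (a tested invariant). The default population
prevalence is 0.10, the lower edge of the 10–15% rate assumed for
persistent non-specific back pain in Germany.

Likelihood ratios are banded for test efficiency (PLR ≥ 10 / 5–10 / 2–5 /
1–2 very high / high / moderate / low; NLR < 0.1 / 0.1–0.2 / 0.2–0.5 /
0.5–1 analogously); the published band edges overlap at their endpoints,
resolved here as half-open intervals. AUCs and sensitivity/specificity
levels (in %) are banded < 70 / 70–80 / 80–90 / ≥ 90 as low / moderate /
good / very good, with the analogous sum-bands at 140/160/180. All
computations keep full precision; presentation rounds half away from zero
to two decimals.

One-way ANOVA (baseline totals across recovered vs. not recovered)
precedes the ROC block as a preliminary check of group separation; the F
decomposition is delegated to `scipy.stats.f_oneway` behind a wrapper that
adds degrees of freedom and rejects degenerate input.

## Synthetic cohorts

No patient-level data is distributed with the study, so the generator
produces cohorts with the structure the analysis assumes; its defaults ARE
the study's conditions: 265 analyzable baselines, invalid-record rate
24/265 per instrument, follow-up return 133/265, outcome prevalences
0.50/0.37/0.52/0.70, target AUCs 0.785/0.738/0.818/0.678, work-item
checkbox missingness 46/(265·3) per item, and a 17/133 missing rate on the
follow-up sick-days item.

Mechanics: a latent chronicity risk θ ~ N(0,1) drives every scored item as
a discretized, range-clipped affine function of θ (loading 0.5 of the item
latent's variance) plus independent noise; reverse-coded items load
negatively on the raw scale. Each outcome state is a Gaussian liability
threshold `D = 1{rθ + √(1−r²)η > z}` with z fixed by the prevalence, so the
configured prevalence holds exactly in expectation. The liability–risk
correlation r is solved numerically (Brent's method on a trivariate-normal
orthant expression for the AUC of a correlated normal marker) so that the
*observed* questionnaire total hits the target AUC; the attenuation
ρ = corr(total, θ) < 1 caused by discretization, clipping and substitution
is estimated once from a fixed-seed calibration draw of 8 000 records and
divided out. A binormal-shortcut design (imposing Δ = √2·Φ⁻¹(AUC) on the
latent) was rejected: with one shared total and several outcomes it cannot
hold per outcome, and discretized totals attenuate it; the liability
construction recovers all four AUCs within 0.003 at n = 40 000. The helper
pair `effect_size_for_auc` / `auc_for_effect_size` exposes the binormal
identity itself.

Follow-up key variables are drawn conditional on the true state, by
construction consistent with the dichotomization cut-offs (rejection
sampling with a deterministic in-range fallback). Follow-up return is
missing-completely-at-random by default; `dropout_risk_slope` makes return
probability fall with θ for sensitivity analyses of selection bias.
Invalid baselines delete more scored items than substitution allows
(ÖMPSQ) or at least one scored item (HKF). One master seed feeds a
per-stage `SeedSequence`, so output is byte-reproducible and stages can be
regenerated independently.

What the generator does **not** emulate: realistic item-level marginals or
the Zung/KSI factor covariance (calibration targets only the total score's
discrimination), free-text commentary on work items, and any systematic
(non-random) missingness mechanism beyond the optional dropout slope.
Passing tests therefore demonstrate correctness of the analysis machinery
under the study's statistical structure, not psychometric realism of the
instruments.

## Problem sizes and numerical choices

The packaged analysis scripts use a 265-baseline cohort (the study size)
for the narrative run and 5 000 baselines for parameter recovery; at the
resulting per-outcome sub-samples (~2 000–2 300 after 50% return and
validation) the AUC standard error is ≈ 0.011, so recovery is verified to
±0.02 per outcome and prevalences to binomial 99% intervals. Liability
correlations are solved to 1e-6; the trivariate-normal CDF uses scipy's
default tolerances; AUC equality with the exhaustive pairwise oracle is
asserted to 1e-12 on samples up to 200 points. Degenerate inputs
(single-class samples, empty groups, zero variance, non-finite scores)
raise structured errors rather than producing NaNs.

## Known limitations

* The HKF-R 10 ships synthetic weights; absolute HKF scores and category
  frequencies are meaningful only with the genuine coefficient table.
* The study's own optimal cut-off locations (84/92/72/46), AUC values and
  p-values depend on the undistributed raw scores and are not reproduced;
  what is reproduced exactly is everything derivable from the printed
  confusion matrices and the Bayes adjustment.
* Coordinate-table cut-offs are midpoints between observed scores; other
  software may print observed values instead, shifting reported (not
  substantive) cut-off locations.
* The ANOVA is the study's preliminary two-group comparison; no post-hoc
  tests or effect sizes beyond F are computed, and correlated-AUC
  comparisons between the two instruments are deliberately out of scope.
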