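"""Diagnostic-validity engine: ROC coordinates, AUC, Youden cut-offs,
likelihood ratios, predictive values and their prevalence adjustment.

Conventions
-----------
Higher questionnaire score means higher risk; a subject is test-positive
when ``score >= cutoff`` (flip with ``positive_ge=False`` for the strict
inequality). "Diseased" is the not-recovered outcome state. Candidate
cut-offs for the coordinate table are the midpoints between consecutive
distinct observed scores plus one sentinel below the minimum and one above
the maximum — the convention of the classic statistics-package coordinate
tables — giving n+1 candidates for n distinct scores.

AUC is the tie-aware Mann–Whitney probability
``P(X_D > X_N) + 0.5 P(X_D = X_N)``; its standard error uses the
Hanley–McNeil distribution-free formula, the null test against 0.5 is an
asymptotic normal z-test, and the 95% CI is ``auc ± 1.96 se`` clipped to
[0, 1]. An exact Mann–Whitney p-value is available for small samples as a
cross-check. All metrics are computed in full precision; rounding
(half away from zero, 2 decimals) happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "ConfusionMatrix",
    "RocPoint",
    "RocCurve",
    "PrevalenceAdjustedPV",
    "confusion_at_cutoff",
    "metrics",
    "roc_coordinates",
    "auc_stats",
    "auc_exact_p",
    "youden_optimal",
    "adjust_pv",
    "classify_plr",
    "classify_nlr",
    "classify_efficiency",
    "classify_quality",
    "classify_quality_sum",
    "round2",
]


def round2(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation only)."""
    if x is None or not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise DegenerateDataError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.tn + self.fp


@dataclass
class RocPoint:
    """Cut-off-associated metric bundle (one coordinate-table row)."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    plr: float
    nlr: float
    ppv: float      # NaN when no test-positives
    npv: float      # NaN when no test-negatives
    accuracy: float
    prevalence: float


@dataclass
class RocCurve:
    points: list[RocPoint]
    auc: float
    se: float
    p_vs_half: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class PrevalenceAdjustedPV:
    prevalence: float
    ppv: float
    npv: float


def _as_arrays(scores, diseased):
    s = np.asarray(scores, dtype=float)
    d = np.asarray(diseased, dtype=bool)
    if s.ndim != 1 or s.shape != d.shape:
        raise ValueError("scores and diseased must be equal-length 1-D sequences")
    if s.size == 0:
        raise DegenerateDataError("empty sample")
    return s, d


def _require_both_classes(d: np.ndarray):
    if d.all() or (~d).all():
        raise DegenerateDataError(
            "both outcome states are required (single-class sample)"
        )


def confusion_at_cutoff(scores, diseased, cutoff: float, positive_ge: bool = True) -> ConfusionMatrix:
    """Cross-classify test result (score vs. cut-off) against outcome state."""
    s, d = _as_arrays(scores, diseased)
    pos = s >= cutoff if positive_ge else s > cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pos & d)),
        fp=int(np.sum(pos & ~d)),
        tn=int(np.sum(~pos & ~d)),
        fn=int(np.sum(~pos & d)),
    )


def metrics(cm: ConfusionMatrix, cutoff: float = math.nan) -> RocPoint:
    """All cut-off-associated validity parameters of one confusion matrix.

    Division by zero yields ``inf`` for likelihood ratios and ``nan``
    (undefined) for predictive values, never an exception.
    """
    if cm.diseased == 0 or cm.non_diseased == 0:
        raise DegenerateDataError("metrics need at least one subject in each state")
    sens = cm.tp / cm.diseased
    spec = cm.tn / cm.non_diseased
    plr = math.inf if spec == 1.0 else sens / (1.0 - spec)
    nlr = math.inf if spec == 0.0 else (1.0 - sens) / spec
    ppv = math.nan if (cm.tp + cm.fp) == 0 else cm.tp / (cm.tp + cm.fp)
    npv = math.nan if (cm.tn + cm.fn) == 0 else cm.tn / (cm.tn + cm.fn)
    return RocPoint(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        plr=plr,
        nlr=nlr,
        ppv=ppv,
        npv=npv,
        accuracy=(cm.tp + cm.tn) / cm.n,
        prevalence=cm.diseased / cm.n,
    )


def candidate_cutoffs(scores) -> np.ndarray:
    """Midpoints between consecutive distinct scores plus ±sentinels."""
    u = np.unique(np.asarray(scores, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def auc_stats(scores, diseased) -> tuple[float, float, float, tuple[float, float]]:
    """Tie-aware Mann–Whitney AUC with Hanley–McNeil SE, z-test vs 0.5, 95% CI."""
    s, d = _as_arrays(scores, diseased)
    _require_both_classes(d)
    n1 = int(d.sum())        # diseased
    n0 = int((~d).sum())
    ranks = stats.rankdata(s)  # midranks: ties counted half
    r1 = ranks[d].sum()
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc) + (n0 - 1) * (q2 - auc * auc)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        z = (auc - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return float(auc), float(se), float(p), (float(lo), float(hi))


def auc_exact_p(scores, diseased) -> float:
    """Exact Mann–Whitney p-value (small-sample cross-check for the z-test)."""
    s, d = _as_arrays(scores, diseased)
    _require_both_classes(d)
    res = stats.mannwhitneyu(s[d], s[~d], alternative="two-sided", method="exact")
    return float(res.pvalue)


def roc_coordinates(scores, diseased, positive_ge: bool = True) -> RocCurve:
    """Full coordinate table (one RocPoint per candidate cut-off) plus AUC block."""
    s, d = _as_arrays(scores, diseased)
    _require_both_classes(d)
    points = [
        metrics(confusion_at_cutoff(s, d, c, positive_ge), cutoff=float(c))
        for c in candidate_cutoffs(s)
    ]
    auc, se, p, ci = auc_stats(s, d)
    return RocCurve(points=points, auc=auc, se=se, p_vs_half=p, ci95=ci)


def youden_optimal(curve: RocCurve) -> RocPoint:
    """The coordinate point maximizing J = sensitivity + specificity - 1;
    ties broken toward the smallest cut-off."""
    if not curve.points:
        raise DegenerateDataError("empty ROC curve")
    best = curve.points[0]
    for p in curve.points:
        if p.youden_j > best.youden_j or (p.youden_j == best.youden_j and p.cutoff < best.cutoff):
            best = p
    return best


def adjust_pv(plr: float, nlr: float, prevalence: float) -> PrevalenceAdjustedPV:
    """Re-compute PPV/NPV at an arbitrary pre-test prevalence via the odds form
    of Bayes' theorem: post-odds(+) = pre-odds × PLR, post-odds(−) = pre-odds × NLR."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1): {prevalence!r}")
    if plr < 0 or nlr < 0:
        raise ValueError("likelihood ratios must be non-negative")
    pre_odds = prevalence / (1.0 - prevalence)
    ppv = 1.0 if math.isinf(plr) else (pre_odds * plr) / (1.0 + pre_odds * plr)
    npv = 0.0 if math.isinf(nlr) else 1.0 / (1.0 + pre_odds * nlr)
    return PrevalenceAdjustedPV(prevalence=prevalence, ppv=ppv, npv=npv)


# Test-efficiency bands for likelihood ratios. Printed band edges overlap
# ("5-10" vs "> 10"); resolved as half-open intervals.
def classify_plr(plr: float) -> str:
    if plr < 1.0:
        return "uninformative"
    if plr < 2.0:
        return "low"
    if plr < 5.0:
        return "moderate"
    if plr < 10.0:
        return "high"
    return "very_high"


def classify_nlr(nlr: float) -> str:
    if nlr > 1.0:
        return "uninformative"
    if nlr >= 0.5:
        return "low"
    if nlr >= 0.2:
        return "moderate"
    if nlr >= 0.1:
        return "high"
    return "very_high"


def classify_efficiency(plr: float, nlr: float) -> tuple[str, str]:
    return classify_plr(plr), classify_nlr(nlr)


def classify_quality(value_pct: float) -> str:
    """Quality band of an AUC or a single sensitivity/specificity, in percent."""
    if not (0.0 <= value_pct <= 100.0):
        raise ValueError(f"percentage out of range: {value_pct!r}")
    if value_pct < 70.0:
        return "low"
    if value_pct < 80.0:
        return "moderate"
    if value_pct < 90.0:
        return "good"
    return "very_good"


def classify_quality_sum(sum_pct: float) -> str:
    """Quality band of sensitivity + specificity (percent sum, max 200)."""
    if not (0.0 <= sum_pct <= 200.0):
        raise ValueError(f"percentage sum out of range: {sum_pct!r}")
    if sum_pct < 140.0:
        return "low"
    if sum_pct < 160.0:
        return "moderate"
    if sum_pct < 180.0:
        return "good"
    return "very_good"
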