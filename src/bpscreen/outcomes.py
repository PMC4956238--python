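"""Six-month outcome dichotomization.

ROC analysis needs binary states, so each follow-up key variable is
thresholded into recovered (test-negative) / not recovered (test-positive):

* ÖMPSQ pain: product of pain intensity × pain frequency over the last three
  months (items 10 and 11, range 0-100); recovered iff product < 17.
* ÖMPSQ function: sum of the five activity items 21-25 as RAW values
  (range 0-50, 10 = best function — deliberately not reverse-coded, unlike
  baseline scoring, so that high sums mean recovery); recovered iff sum >= 45.
* ÖMPSQ sick leave: self-reported sick-leave days over the follow-up window;
  recovered iff 0 days. A descriptive trichotomy (none / 1-30 / > 30 days)
  is kept alongside.
* HKF pain: last-week pain VAS (HKF item 5, 0-100); recovered iff VAS < 30.

A record missing an outcome's inputs simply has no label for that outcome
and drops from the outcome's sub-sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DegenerateDataError
from .ompsq import _is_missing

__all__ = [
    "OUTCOMES",
    "FollowUpRecord",
    "OutcomeLabel",
    "Subsample",
    "dichotomize_pain_ompsq",
    "dichotomize_function",
    "dichotomize_sickleave",
    "trichotomize_sickleave",
    "dichotomize_pain_hkf",
    "label_followup",
    "build_subsamples",
]

#: analysis outcomes in report order
OUTCOMES = ("ompsq_pain", "ompsq_sickleave", "ompsq_function", "hkf_pain")

PAIN_PRODUCT_CUTOFF = 17.0     # recovered below
FUNCTION_SUM_CUTOFF = 45.0     # recovered at or above
HKF_VAS_CUTOFF = 30.0          # recovered below
SHORT_TERM_MAX_DAYS = 30


@dataclass
class FollowUpRecord:
    participant_id: str
    pain_intensity: Optional[float] = None       # item 10, 0-10
    pain_frequency: Optional[float] = None       # item 11, 0-10
    function_items: Optional[Sequence[Optional[float]]] = None  # items 21-25 raw
    sick_leave_days: Optional[int] = None
    hkf_pain_vas: Optional[float] = None         # HKF item 5, 0-100


@dataclass(frozen=True)
class OutcomeLabel:
    outcome: str
    recovered: bool
    raw_value: float


def dichotomize_pain_ompsq(i10, i11) -> Optional[OutcomeLabel]:
    if _is_missing(i10) or _is_missing(i11):
        return None
    product = float(i10) * float(i11)
    return OutcomeLabel("ompsq_pain", recovered=product < PAIN_PRODUCT_CUTOFF, raw_value=product)


def dichotomize_function(items) -> Optional[OutcomeLabel]:
    if items is None or len(items) != 5 or any(_is_missing(v) for v in items):
        return None
    total = float(sum(float(v) for v in items))
    return OutcomeLabel("ompsq_function", recovered=total >= FUNCTION_SUM_CUTOFF, raw_value=total)


def dichotomize_sickleave(days) -> Optional[OutcomeLabel]:
    if _is_missing(days):
        return None
    days = int(days)
    if days < 0:
        raise ValueError(f"negative sick-leave days: {days}")
    return OutcomeLabel("ompsq_sickleave", recovered=days == 0, raw_value=float(days))


def trichotomize_sickleave(days) -> Optional[str]:
    if _is_missing(days):
        return None
    days = int(days)
    if days < 0:
        raise ValueError(f"negative sick-leave days: {days}")
    if days == 0:
        return "none"
    if days <= SHORT_TERM_MAX_DAYS:
        return "short_term"
    return "long_term"


def dichotomize_pain_hkf(vas) -> Optional[OutcomeLabel]:
    if _is_missing(vas):
        return None
    return OutcomeLabel("hkf_pain", recovered=float(vas) < HKF_VAS_CUTOFF, raw_value=float(vas))


def label_followup(rec: FollowUpRecord) -> dict[str, OutcomeLabel]:
    """All labels derivable from one follow-up record (absent where inputs are)."""
    labels = {
        "ompsq_pain": dichotomize_pain_ompsq(rec.pain_intensity, rec.pain_frequency),
        "ompsq_function": dichotomize_function(rec.function_items),
        "ompsq_sickleave": dichotomize_sickleave(rec.sick_leave_days),
        "hkf_pain": dichotomize_pain_hkf(rec.hkf_pain_vas),
    }
    return {k: v for k, v in labels.items() if v is not None}


@dataclass
class Subsample:
    """One outcome's paired analysis set: baseline score vs. binary state.

    ``diseased`` is the test-positive truth (not recovered)."""

    outcome: str
    ids: list[str]
    scores: np.ndarray
    diseased: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def prevalence(self) -> float:
        if self.n == 0:
            raise DegenerateDataError(f"empty sub-sample for {self.outcome}")
        return float(np.mean(self.diseased))


def build_subsamples(
    ompsq_totals: Iterable[tuple[str, float]],
    hkf_scores: Iterable[tuple[str, float]],
    labels: Mapping[str, Mapping[str, OutcomeLabel]],
) -> dict[str, Subsample]:
    """Intersect valid baseline scores with present follow-up labels.

    ``labels`` maps participant_id -> outcome -> label. Raises on duplicate
    participant ids within either score list.
    """
    score_maps = {}
    for name, pairs in (("ompsq", ompsq_totals), ("hkf", hkf_scores)):
        m: dict[str, float] = {}
        for pid, score in pairs:
            if pid in m:
                raise DegenerateDataError(f"duplicate participant id {pid!r} in {name} scores")
            m[pid] = float(score)
        score_maps[name] = m

    out: dict[str, Subsample] = {}
    for outcome in OUTCOMES:
        source = score_maps["hkf"] if outcome == "hkf_pain" else score_maps["ompsq"]
        ids, scores, diseased = [], [], []
        for pid, score in source.items():
            lab = labels.get(pid, {}).get(outcome)
            if lab is None:
                continue
            ids.append(pid)
            scores.append(score)
            diseased.append(not lab.recovered)
        out[outcome] = Subsample(
            outcome=outcome,
            ids=ids,
            scores=np.asarray(scores, dtype=float),
            diseased=np.asarray(diseased, dtype=bool),
        )
    return out
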