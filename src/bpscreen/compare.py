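"""Preliminary group comparison: one-way ANOVA of baseline totals across
outcome groups (recovered vs. not recovered).

A clear baseline-score separation between the groups is the precondition for
any cut-off to discriminate; the F-test quantifies it before ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = ["AnovaResult", "oneway_anova"]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard one-way decomposition; F = (SSB/dfB)/(SSW/dfW), upper-tail p.

    Degenerate inputs (fewer than two groups, an empty group, zero total
    variance, no residual degrees of freedom) raise
    :class:`DegenerateDataError` rather than returning NaNs.
    """
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA needs at least two groups")
    arrays = []
    for label, values in groups.items():
        a = np.asarray(values, dtype=float)
        if a.size == 0:
            raise DegenerateDataError(f"group {label!r} is empty")
        arrays.append(a)
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise DegenerateDataError("no residual degrees of freedom")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        raise DegenerateDataError("zero total variance")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(f=float(f), df_between=k - 1, df_within=n_total - k, p=float(p))
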