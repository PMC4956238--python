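"""Synthetic back-pain screening cohorts.

No raw patient data accompanies the validation study this pipeline
implements, so this module generates cohorts with the statistical structure
the analysis assumes: a latent chronicity risk drives both questionnaires'
item responses and, through correlated liabilities, the four six-month
outcome states. Every pipeline stage — scoring, validation bookkeeping,
outcome labelling, ROC analysis — can then run end to end, and parameter
recovery (prevalences, AUCs) is checkable against the configuration.

Model
-----
* Latent risk ``theta_i ~ N(0, 1)``.
* Each scored item is a discretized, range-clipped affine function of theta
  plus independent noise (loading 0.5 of the latent variance); reverse-coded
  items load negatively on the raw scale so risk always raises the
  transformed value. Calibration targets the TOTAL score's discrimination,
  not item-level realism.
* Each outcome state is a Gaussian liability threshold:
  ``D = 1{r·theta + sqrt(1-r²)·eta > z}`` with ``z`` fixed by the configured
  prevalence (exact marginal). The liability correlation ``r`` is solved
  numerically so that the OBSERVED questionnaire total attains the
  configured AUC against ``D``, after correcting for the attenuation
  ``rho = corr(total, theta)`` estimated once from a fixed-seed calibration
  draw (discretization and clipping make rho < 1).
* Follow-up return is missing-completely-at-random at ``followup_rate``
  (an optional risk-dependent dropout slope models the selection bias a
  postal follow-up may suffer); invalid baselines delete more scored items
  than substitution allows; "not working" checkbox missingness hits the
  three work items independently at ``checkbox_rate``.
* Follow-up key variables are drawn conditional on the true outcome state
  (consistent by construction with the dichotomization cut-offs).

One master seed feeds a per-stage seed sequence, so output is fully
reproducible and stages are independently regenerable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError
from .hkf import HkfWeightSpec, default_manifest, load_weights
from .ompsq import OmpsqInstrument, default_instrument
from .outcomes import OUTCOMES

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate",
    "effect_size_for_auc",
    "auc_for_effect_size",
    "liability_auc",
]

_ITEM_LOADING = 0.5      # share of each item latent's variance carried by theta
_CAL_N = 8000            # size of the fixed attenuation-calibration draw
_CAL_SEED = 718293


def _default_prevalences() -> dict[str, float]:
    return {
        "ompsq_pain": 0.50,
        "ompsq_sickleave": 0.37,
        "ompsq_function": 0.52,
        "hkf_pain": 0.70,
    }


def _default_aucs() -> dict[str, float]:
    return {
        "ompsq_pain": 0.785,
        "ompsq_sickleave": 0.738,
        "ompsq_function": 0.818,
        "hkf_pain": 0.678,
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All generator knobs. Defaults emulate the study cohort: 265 analyzable
    baselines, ~9% invalid records, ~50% follow-up return, the four observed
    outcome prevalences and AUC levels, and checkbox missingness informed by
    the 46 reported "not working" substitutions."""

    n_baseline: int = 265
    invalid_rate: float = 24 / 265
    followup_rate: float = 133 / 265
    outcome_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    target_auc: dict[str, float] = field(default_factory=_default_aucs)
    checkbox_rate: float = 46 / 265 / 3
    sickdays_missing_rate: float = 17 / 133
    dropout_risk_slope: float = 0.0   # >0 makes high-risk subjects drop out more
    seed: int = 0

    def validate(self) -> None:
        if self.n_baseline < 1:
            raise ConfigError("n_baseline must be positive")
        for name, p in [
            ("invalid_rate", self.invalid_rate),
            ("followup_rate", self.followup_rate),
            ("checkbox_rate", self.checkbox_rate),
            ("sickdays_missing_rate", self.sickdays_missing_rate),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]: {p!r}")
        if set(self.outcome_prevalences) != set(OUTCOMES) or set(self.target_auc) != set(OUTCOMES):
            raise ConfigError(f"prevalence/AUC maps must cover outcomes {OUTCOMES}")
        for o in OUTCOMES:
            if not (0.0 < self.outcome_prevalences[o] < 1.0):
                raise ConfigError(f"prevalence for {o} must lie in (0, 1)")
            if not (0.5 < self.target_auc[o] < 1.0):
                raise ConfigError(f"target AUC for {o} must lie in (0.5, 1)")


@dataclass
class SyntheticCohort:
    baseline: pd.DataFrame
    followup: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(out / "baseline.csv", index=False)
        self.followup.to_csv(out / "followup.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# binormal helpers

def effect_size_for_auc(auc: float) -> float:
    """Binormal separation Delta with AUC = Phi(Delta / sqrt(2))."""
    if not (0.5 < auc < 1.0):
        raise ValueError(f"auc must lie in (0.5, 1): {auc!r}")
    return math.sqrt(2.0) * float(stats.norm.ppf(auc))


def auc_for_effect_size(delta: float) -> float:
    """Inverse of :func:`effect_size_for_auc`."""
    return float(stats.norm.cdf(delta / math.sqrt(2.0)))


def liability_auc(marker_liability_corr: float, prevalence: float) -> float:
    """AUC of a standard-normal marker against a liability-threshold state.

    The marker X and liability L are bivariate standard normal with the given
    correlation c; the state is ``D = 1{L > z}`` with ``P(D) = prevalence``.
    Writing ``W = (X1 - X2)/sqrt(2)`` for independent subjects, the AUC is the
    trivariate-normal orthant probability
    ``P(W > 0, L1 > z, L2 <= z) / (prev (1 - prev))``.
    """
    c = float(marker_liability_corr)
    if not (0.0 <= c < 1.0):
        raise ValueError(f"correlation must lie in [0, 1): {c!r}")
    p = float(prevalence)
    z = stats.norm.ppf(1.0 - p)
    rw = c / math.sqrt(2.0)
    p2 = stats.multivariate_normal(cov=[[1.0, rw], [rw, 1.0]], allow_singular=True).cdf([0.0, -z])
    cov3 = [[1.0, rw, -rw], [rw, 1.0, 0.0], [-rw, 0.0, 1.0]]
    p3 = stats.multivariate_normal(cov=cov3, allow_singular=True).cdf([0.0, -z, -z])
    return float((p2 - p3) / (p * (1.0 - p)))


def _solve_marker_corr(target_auc: float, prevalence: float) -> float:
    """Marker-liability correlation c with liability_auc(c, prev) = target."""
    f = lambda c: liability_auc(c, prevalence) - target_auc
    return float(optimize.brentq(f, 1e-6, 1.0 - 1e-9, xtol=1e-6))


# ---------------------------------------------------------------------------
# item response models

def _item_latent(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(theta.shape[0])
    return math.sqrt(_ITEM_LOADING) * theta + math.sqrt(1.0 - _ITEM_LOADING) * eps


def _ompsq_raw_matrix(
    theta: np.ndarray, rng: np.random.Generator, inst: OmpsqInstrument
) -> np.ndarray:
    """Raw responses, one column per scored item in instrument order."""
    n = theta.shape[0]
    cols = np.empty((n, len(inst.items)))
    for j, spec in enumerate(inst.items):
        lat = _item_latent(theta, rng)
        if spec.doubled:                      # pain-sites categories
            raw = np.rint(3.5 + 1.2 * lat)
        elif spec.scale_min == 1:
            raw = np.rint(5.5 + 2.2 * lat)
        elif spec.inverted:                   # risk lowers the raw mark
            raw = np.rint(5.0 - 2.2 * lat)
        else:
            raw = np.rint(5.0 + 2.2 * lat)
        cols[:, j] = np.clip(raw, spec.scale_min, spec.scale_max)
    return cols


def _hkf_item_matrix(
    theta: np.ndarray, rng: np.random.Generator, weights: HkfWeightSpec
) -> pd.DataFrame:
    """All 27 HKF items; scored items load on theta with the sign of their
    weight so risk always raises the weighted score."""
    manifest = default_manifest()
    w_by_item = {}
    for t in weights.terms:
        for i in t.target:
            w_by_item[i] = t.weight
    n = theta.shape[0]
    data = {}
    for spec in manifest.items:
        if spec.item_id == 1:                 # gender, independent demographic
            data[spec.item_id] = rng.binomial(1, 0.65, n).astype(float)
        elif spec.item_id == 2:               # graduation, independent
            data[spec.item_id] = np.clip(np.rint(2.0 + 1.2 * rng.standard_normal(n)), 0, 4)
        elif not spec.scored:                 # item 5: last-week pain VAS
            lat = _item_latent(theta, rng)
            data[spec.item_id] = np.clip(np.rint(50.0 + 20.0 * lat), 0, 100)
        else:
            sign = 1.0 if w_by_item.get(spec.item_id, 1.0) >= 0 else -1.0
            lat = _item_latent(theta, rng)
            data[spec.item_id] = np.clip(np.rint(5.0 + sign * 2.2 * lat), 0, 10)
    return pd.DataFrame(data)


def _vector_ompsq_totals(raw: np.ndarray, missing: np.ndarray, inst: OmpsqInstrument) -> np.ndarray:
    """Vectorized scoring (transform + mean substitution) for calibration and
    truth bookkeeping; must agree with :func:`bpscreen.ompsq.score_ompsq`."""
    transformed = raw.copy()
    for j, spec in enumerate(inst.items):
        if spec.inverted:
            transformed[:, j] = 10.0 - transformed[:, j]
        if spec.doubled:
            transformed[:, j] = 2.0 * transformed[:, j]
    present = ~missing
    n_present = present.sum(axis=1)
    sums = np.where(present, transformed, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        totals = sums / n_present * len(inst.items)
    return totals


def _hkf_scores_vector(items: pd.DataFrame, weights: HkfWeightSpec) -> np.ndarray:
    s = np.full(len(items), weights.intercept)
    for t in weights.terms:
        for i in t.target:
            s = s + t.weight * items[i].to_numpy()
    return s


# ---------------------------------------------------------------------------
# attenuation calibration (fixed-seed, cached)

@lru_cache(maxsize=16)
def _ompsq_attenuation(checkbox_rate: float) -> float:
    """corr(observed scored total, theta) under the item model, including
    checkbox missingness and mean substitution."""
    inst = default_instrument()
    rng = np.random.default_rng(
        np.random.SeedSequence([_CAL_SEED, 1, int(round(checkbox_rate * 1e9))])
    )
    theta = rng.standard_normal(_CAL_N)
    raw = _ompsq_raw_matrix(theta, rng, inst)
    missing = np.zeros_like(raw, dtype=bool)
    if checkbox_rate > 0:
        cb_cols = [j for j, s in enumerate(inst.items) if s.checkbox_allowed]
        for j in cb_cols:
            missing[:, j] = rng.random(_CAL_N) < checkbox_rate
    totals = _vector_ompsq_totals(raw, missing, inst)
    return float(np.corrcoef(totals, theta)[0, 1])


@lru_cache(maxsize=1)
def _hkf_attenuation() -> float:
    weights = load_weights()
    rng = np.random.default_rng(np.random.SeedSequence([_CAL_SEED, 2]))
    theta = rng.standard_normal(_CAL_N)
    items = _hkf_item_matrix(theta, rng, weights)
    scores = _hkf_scores_vector(items, weights)
    return float(np.corrcoef(scores, theta)[0, 1])


def _liability_corr(target_auc: float, prevalence: float, attenuation: float, outcome: str) -> float:
    c = _solve_marker_corr(target_auc, prevalence)
    r = c / attenuation
    if r >= 1.0:
        raise ConfigError(
            f"target AUC {target_auc} for {outcome} is unreachable: the item model "
            f"attenuates the total-score signal to {attenuation:.3f} of the latent"
        )
    return r


# ---------------------------------------------------------------------------
# follow-up key variables conditional on the true state

def _reject_draw(rng, n, draw, ok, fallback, max_iter=200):
    """Vectorized rejection sampling with a deterministic fallback."""
    vals = draw(n)
    bad = ~ok(vals)
    it = 0
    while bad.any() and it < max_iter:
        redraw = draw(int(bad.sum()))
        vals[bad] = redraw
        bad = ~ok(vals)
        it += 1
    if bad.any():
        vals[bad] = fallback
    return vals


def _followup_frame(
    ids: list[str],
    states: dict[str, np.ndarray],
    rng: np.random.Generator,
    sickdays_missing_rate: float,
) -> pd.DataFrame:
    n = len(ids)

    def pain_pair(diseased: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        def draw_pair(m, mean, sd):
            a = np.clip(np.rint(rng.normal(mean, sd, m)), 0, 10)
            b = np.clip(np.rint(rng.normal(mean, sd, m)), 0, 10)
            return np.stack([a, b], axis=1)

        out = np.empty((n, 2))
        for flag, mean, sd, fb in [(True, 6.5, 2.0, (5.0, 4.0)), (False, 2.5, 1.8, (2.0, 2.0))]:
            idx = np.where(diseased == flag)[0]
            want_pos = flag

            def drawer(m, mean=mean, sd=sd):
                return draw_pair(m, mean, sd)

            def okfun(v, want=want_pos):
                return ((v[:, 0] * v[:, 1]) >= 17.0) == want

            out[idx] = _reject_draw(rng, len(idx), drawer, okfun, np.array(fb))
        return out[:, 0], out[:, 1]

    def function_items(diseased: np.ndarray) -> np.ndarray:
        out = np.empty((n, 5))
        for flag, mean, sd, fb in [
            (True, 6.0, 2.0, np.full(5, 8.0)),    # sum 40 < 45
            (False, 9.4, 1.0, np.full(5, 9.0)),   # sum 45 >= 45
        ]:
            idx = np.where(diseased == flag)[0]

            def drawer(m, mean=mean, sd=sd):
                return np.clip(np.rint(rng.normal(mean, sd, (m, 5))), 0, 10)

            def okfun(v, want=flag):
                return (v.sum(axis=1) < 45.0) == want

            out[idx] = _reject_draw(rng, len(idx), drawer, okfun, fb)
        return out

    def sick_days(diseased: np.ndarray) -> np.ndarray:
        days = np.zeros(n)
        idx = np.where(diseased)[0]
        days[idx] = 1.0 + np.floor(rng.lognormal(2.0, 1.2, len(idx)))
        return np.clip(days, 0, 365)

    def hkf_vas(diseased: np.ndarray) -> np.ndarray:
        vas = np.empty(n)
        idx_d = np.where(diseased)[0]
        idx_r = np.where(~diseased)[0]
        vas[idx_d] = np.clip(np.rint(rng.normal(52.0, 16.0, len(idx_d))), 30, 100)
        vas[idx_r] = np.clip(np.rint(rng.normal(14.0, 9.0, len(idx_r))), 0, 29)
        return vas

    i10, i11 = pain_pair(states["ompsq_pain"])
    func = function_items(states["ompsq_function"])
    days = sick_days(states["ompsq_sickleave"])
    vas = hkf_vas(states["hkf_pain"])

    frame = pd.DataFrame({"id": ids, "fu_omp_10": i10, "fu_omp_11": i11})
    for k in range(5):
        frame[f"fu_omp_{21 + k}"] = func[:, k]
    frame["fu_sickdays"] = days
    frame["fu_hkf_5"] = vas
    if sickdays_missing_rate > 0:
        miss = rng.random(n) < sickdays_missing_rate
        frame.loc[miss, "fu_sickdays"] = np.nan
    return frame


# ---------------------------------------------------------------------------

def generate(config: Optional[SyntheticCohortConfig] = None, **overrides) -> SyntheticCohort:
    """Generate a full baseline + follow-up cohort with a truth table."""
    if config is None:
        config = SyntheticCohortConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    inst = default_instrument()
    weights = load_weights()
    n = config.n_baseline

    ss = np.random.SeedSequence(config.seed)
    (s_theta, s_omp, s_hkf, s_cb, s_inv, s_state, s_fu, s_out) = ss.spawn(8)
    rng_theta = np.random.default_rng(s_theta)
    rng_omp = np.random.default_rng(s_omp)
    rng_hkf = np.random.default_rng(s_hkf)
    rng_cb = np.random.default_rng(s_cb)
    rng_inv = np.random.default_rng(s_inv)
    rng_state = np.random.default_rng(s_state)
    rng_fu = np.random.default_rng(s_fu)
    rng_out = np.random.default_rng(s_out)

    theta = rng_theta.standard_normal(n)
    ids = [f"R{i:05d}" for i in range(n)]

    # --- baseline item responses
    omp_raw = _ompsq_raw_matrix(theta, rng_omp, inst)
    hkf_items = _hkf_item_matrix(theta, rng_hkf, weights)

    # checkbox missingness on the work items
    cb_ticked = {s.item_id: np.zeros(n, dtype=bool) for s in inst.items if s.checkbox_allowed}
    omp_missing = np.zeros_like(omp_raw, dtype=bool)
    for j, spec in enumerate(inst.items):
        if spec.checkbox_allowed and config.checkbox_rate > 0:
            hit = rng_cb.random(n) < config.checkbox_rate
            cb_ticked[spec.item_id] = hit
            omp_missing[:, j] |= hit

    # invalid baselines: delete more items than substitution allows
    omp_invalid = rng_inv.random(n) < config.invalid_rate
    for i in np.where(omp_invalid)[0]:
        k = int(rng_inv.integers(inst.max_substitutions + 1, inst.max_substitutions + 5))
        cols = rng_inv.choice(len(inst.items), size=k, replace=False)
        omp_missing[i, cols] = True
        for spec_id, ticked in cb_ticked.items():
            ticked[i] = False  # plain deletion, not checkbox
    hkf_invalid = rng_inv.random(n) < config.invalid_rate
    hkf_scored = default_manifest().scored_ids
    hkf_missing = pd.DataFrame(False, index=range(n), columns=list(hkf_items.columns))
    for i in np.where(hkf_invalid)[0]:
        k = int(rng_inv.integers(1, 4))
        for c in rng_inv.choice(hkf_scored, size=k, replace=False):
            hkf_missing.loc[i, c] = True

    # --- outcome states via calibrated liability thresholds
    rho_omp = _ompsq_attenuation(round(config.checkbox_rate, 9))
    rho_hkf = _hkf_attenuation()
    states: dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        prev = config.outcome_prevalences[outcome]
        rho = rho_hkf if outcome == "hkf_pain" else rho_omp
        r = _liability_corr(config.target_auc[outcome], prev, rho, outcome)
        z = stats.norm.ppf(1.0 - prev)
        liab = r * theta + math.sqrt(1.0 - r * r) * rng_state.standard_normal(n)
        states[outcome] = liab > z

    # --- follow-up return (MCAR by default; optional risk-dependent dropout)
    p_return = np.full(n, config.followup_rate)
    if config.dropout_risk_slope != 0.0:
        logit = math.log(config.followup_rate / (1.0 - config.followup_rate)) \
            - config.dropout_risk_slope * theta
        p_return = 1.0 / (1.0 + np.exp(-logit))
    returned = rng_fu.random(n) < p_return

    # --- assemble frames
    baseline = pd.DataFrame({"id": ids})
    for j, spec in enumerate(inst.items):
        col = omp_raw[:, j].copy()
        col[omp_missing[:, j]] = np.nan
        baseline[f"omp_{spec.item_id}"] = col
    for item_id, ticked in cb_ticked.items():
        baseline[f"omp_{item_id}_nw"] = ticked.astype(int)
    for spec in default_manifest().items:
        col = hkf_items[spec.item_id].to_numpy(dtype=float, copy=True)
        col[hkf_missing[spec.item_id].to_numpy()] = np.nan
        baseline[f"hkf_{spec.item_id}"] = col

    fu_ids = [ids[i] for i in np.where(returned)[0]]
    fu_states = {o: s[returned] for o, s in states.items()}
    followup = _followup_frame(fu_ids, fu_states, rng_out, config.sickdays_missing_rate)

    truth = pd.DataFrame(
        {
            "id": ids,
            "theta": theta,
            "returned": returned.astype(int),
            "ompsq_invalid": omp_invalid.astype(int),
            "hkf_invalid": hkf_invalid.astype(int),
        }
    )
    for outcome in OUTCOMES:
        truth[f"true_{outcome}"] = states[outcome].astype(int)

    return SyntheticCohort(baseline=baseline, followup=followup, truth=truth, config=config)
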