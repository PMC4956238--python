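"""Scoring of the Heidelberger Kurzfragebogen Rückenschmerz (HKF-R 10).

The HKF-R 10 is a short German screening form for risk of persisting
back pain. Its total is a regression-type score: an intercept plus a
weighted sum ("sum products" with positive and negative weights) over the
scored items; the last-week pain VAS (item 5) is recorded but never scored.
Scores map to five fixed risk categories:

    low             score <= -2.5
    probably_low    -2.5 < score <= 8
    no_prediction    8 < score < 28
    probably_high   28 <= score < 37
    high            score >= 37

Missing values are not allowed: an incomplete record is invalid, never
imputed. The item manifest and the weight table are both config files; the
packaged weight file is a synthetic stand-in (the published coefficients are
not reproduced here) so real use requires supplying the genuine table.
The weight spec accepts item-level or group-level terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import yaml

from .errors import ConfigError, InvalidRecordError
from .ompsq import ValidationResult, _is_missing

__all__ = [
    "HkfItemSpec",
    "HkfManifest",
    "HkfResponse",
    "HkfWeightSpec",
    "HkfScore",
    "load_manifest",
    "load_weights",
    "validate_hkf",
    "score_hkf",
    "classify_hkf",
]

CATEGORIES = ("low", "probably_low", "no_prediction", "probably_high", "high")


@dataclass(frozen=True)
class HkfItemSpec:
    item_id: int
    scale_min: float
    scale_max: float
    scored: bool = True


@dataclass(frozen=True)
class HkfManifest:
    items: tuple[HkfItemSpec, ...]

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(s.item_id for s in self.items)

    @property
    def scored_ids(self) -> tuple[int, ...]:
        return tuple(s.item_id for s in self.items if s.scored)

    def spec(self, item_id: int) -> HkfItemSpec:
        for s in self.items:
            if s.item_id == item_id:
                return s
        raise ConfigError(f"item {item_id} not in HKF manifest")


@dataclass
class HkfResponse:
    participant_id: str
    item_values: Mapping[int, Optional[float]]


@dataclass(frozen=True)
class WeightTerm:
    """One term of the score: a single item id or a named group of ids."""

    target: tuple[int, ...]
    weight: float


@dataclass(frozen=True)
class HkfWeightSpec:
    intercept: float
    terms: tuple[WeightTerm, ...]

    def covered_ids(self) -> tuple[int, ...]:
        out: list[int] = []
        for t in self.terms:
            out.extend(t.target)
        return tuple(out)


@dataclass
class HkfScore:
    score: float
    category: str


def load_manifest(path=None) -> HkfManifest:
    if path is None:
        text = resources.files("bpscreen.data").joinpath("hkf_items.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        return HkfManifest(
            tuple(
                HkfItemSpec(
                    item_id=int(d["id"]),
                    scale_min=float(d["scale_min"]),
                    scale_max=float(d["scale_max"]),
                    scored=bool(d.get("scored", True)),
                )
                for d in raw["items"]
            )
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed HKF manifest: {exc}") from exc


def load_weights(path=None) -> HkfWeightSpec:
    """Load a weight spec; the packaged SYNTHETIC placeholder if no path.

    Terms may target one item (``item: 12``) or a group
    (``items: [9, 10, 11]``) whose values are summed before weighting.
    """
    if path is None:
        text = resources.files("bpscreen.data").joinpath(
            "hkf_weights_synthetic.yaml"
        ).read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        terms = []
        for d in raw["terms"]:
            if "item" in d:
                target = (int(d["item"]),)
            else:
                target = tuple(int(i) for i in d["items"])
            terms.append(WeightTerm(target=target, weight=float(d["weight"])))
        return HkfWeightSpec(intercept=float(raw.get("intercept", 0.0)), terms=tuple(terms))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed HKF weight spec: {exc}") from exc


_DEFAULT_MANIFEST: Optional[HkfManifest] = None


def default_manifest() -> HkfManifest:
    global _DEFAULT_MANIFEST
    if _DEFAULT_MANIFEST is None:
        _DEFAULT_MANIFEST = load_manifest()
    return _DEFAULT_MANIFEST


def classify_hkf(score: float) -> str:
    """Map a finite score to exactly one of the five risk categories."""
    if not math.isfinite(score):
        raise ValueError(f"non-finite HKF score: {score!r}")
    if score <= -2.5:
        return "low"
    if score <= 8:
        return "probably_low"
    if score < 28:
        return "no_prediction"
    if score < 37:
        return "probably_high"
    return "high"


def validate_hkf(resp: HkfResponse, manifest: Optional[HkfManifest] = None) -> ValidationResult:
    """Valid iff every scored item is present and in range. A missing item 5
    leaves baseline scoring possible (it is unscored) but is reported so the
    pipeline can drop the record from the pain outcome."""
    manifest = manifest or default_manifest()
    for spec in manifest.items:
        v = resp.item_values.get(spec.item_id)
        if _is_missing(v):
            if spec.scored:
                return ValidationResult(False, f"missing scored item {spec.item_id}")
            continue
        if not (spec.scale_min <= v <= spec.scale_max):
            return ValidationResult(
                False,
                f"item {spec.item_id}: value {v!r} outside [{spec.scale_min}, {spec.scale_max}]",
            )
    return ValidationResult(True)


def score_hkf(
    resp: HkfResponse,
    weights: Optional[HkfWeightSpec] = None,
    manifest: Optional[HkfManifest] = None,
) -> HkfScore:
    """Weighted sum-product score plus its category.

    Raises :class:`InvalidRecordError` for incomplete/out-of-range records and
    :class:`ConfigError` when the weight spec does not cover the scored items
    exactly once.
    """
    manifest = manifest or default_manifest()
    weights = weights or load_weights()
    covered = weights.covered_ids()
    scored = manifest.scored_ids
    if sorted(covered) != sorted(scored):
        raise ConfigError(
            f"weight spec covers items {sorted(covered)} but manifest scores {sorted(scored)}"
        )
    verdict = validate_hkf(resp, manifest)
    if not verdict:
        raise InvalidRecordError(resp.participant_id, verdict.reason or "invalid")
    s = weights.intercept
    for term in weights.terms:
        s += term.weight * sum(float(resp.item_values[i]) for i in term.target)
    return HkfScore(score=s, category=classify_hkf(s))
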