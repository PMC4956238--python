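"""Scoring of the Örebro Musculoskeletal Pain Screening Questionnaire (ÖMPSQ).

The German translation scores 21 of 25 items (IDs 5-25; the four
sociodemographic items are excluded). Most items are 0-10 visual-analogue
ratings; three use a 1-10 scale, of which the pain-sites item has six
categories whose value is counted twice. Eight items are reverse-coded
(transformed value = 10 - raw) so that a higher transformed value always
means higher chronicity risk; the linear total therefore spans 4-212.
Three work-related items carry a "not working" checkbox which, when ticked
without a scale mark, makes the item missing; up to three missing items may
be replaced by the mean of the answered (transformed) items. Totals map to
three risk bands: low (< 91), medium (91-106) and high (> 106).

The whole item table lives in a YAML config (:func:`load_instrument`), so an
alternate numbering or the original Swedish 4-210 variant is a data change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import yaml

from .errors import ConfigError, InvalidRecordError, RangeError

__all__ = [
    "OmpsqItemSpec",
    "OmpsqInstrument",
    "OmpsqResponse",
    "OmpsqScore",
    "ValidationResult",
    "load_instrument",
    "transform_item",
    "resolve_checkbox",
    "substitute_missing",
    "validate_record",
    "score_ompsq",
    "risk_band",
]

MISSING = None  # explicit sentinel; NaN in tabular files parses to this


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class OmpsqItemSpec:
    """Scoring rule for one scored item."""

    item_id: int
    scale_min: int
    scale_max: int
    inverted: bool = False
    doubled: bool = False
    checkbox_allowed: bool = False

    def transformed_bounds(self) -> tuple[float, float]:
        lo, hi = self.scale_min, self.scale_max
        if self.inverted:
            lo, hi = 10 - hi, 10 - lo
        if self.doubled:
            lo, hi = 2 * lo, 2 * hi
        return float(lo), float(hi)


@dataclass(frozen=True)
class OmpsqInstrument:
    """The full scored-item table plus banding and substitution policy."""

    items: tuple[OmpsqItemSpec, ...]
    max_substitutions: int = 3
    band_low_below: float = 91.0
    band_high_upto: float = 106.0

    def __post_init__(self):
        ids = [s.item_id for s in self.items]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate item ids in instrument table")

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(s.item_id for s in self.items)

    @property
    def checkbox_ids(self) -> tuple[int, ...]:
        return tuple(s.item_id for s in self.items if s.checkbox_allowed)

    def spec(self, item_id: int) -> OmpsqItemSpec:
        for s in self.items:
            if s.item_id == item_id:
                return s
        raise ConfigError(f"item {item_id} not in instrument table")

    def total_bounds(self) -> tuple[float, float]:
        los, his = zip(*(s.transformed_bounds() for s in self.items))
        return sum(los), sum(his)


@dataclass
class OmpsqResponse:
    """One participant's raw baseline answers.

    ``raw_values`` maps item id to the raw scale mark or ``None`` when the
    field was left blank; ``checkbox_ticked`` holds the "not working" boxes
    of the checkbox-allowed items.
    """

    participant_id: str
    raw_values: Mapping[int, Optional[float]]
    checkbox_ticked: Mapping[int, bool] = field(default_factory=dict)


@dataclass
class OmpsqScore:
    total: float
    n_substituted: int
    risk_band: str
    per_item_transformed: dict[int, float]


@dataclass
class ValidationResult:
    valid: bool
    reason: Optional[str] = None
    n_missing: int = 0

    def __bool__(self) -> bool:
        return self.valid


def load_instrument(path=None) -> OmpsqInstrument:
    """Load the item table; the packaged German-translation default if no path."""
    if path is None:
        text = resources.files("bpscreen.data").joinpath("ompsq_items.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        items = tuple(
            OmpsqItemSpec(
                item_id=int(d["id"]),
                scale_min=int(d["scale_min"]),
                scale_max=int(d["scale_max"]),
                inverted=bool(d.get("inverted", False)),
                doubled=bool(d.get("doubled", False)),
                checkbox_allowed=bool(d.get("checkbox", False)),
            )
            for d in raw["items"]
        )
        bands = raw.get("risk_bands", {})
        return OmpsqInstrument(
            items=items,
            max_substitutions=int(raw.get("max_substitutions", 3)),
            band_low_below=float(bands.get("low_below", 91)),
            band_high_upto=float(bands.get("high_upto", 106)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed item-spec table: {exc}") from exc


_DEFAULT: Optional[OmpsqInstrument] = None


def default_instrument() -> OmpsqInstrument:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_instrument()
    return _DEFAULT


def transform_item(spec: OmpsqItemSpec, raw: float) -> float:
    """Apply the item's scoring rule: identity, reverse-coding, or doubling."""
    if _is_missing(raw):
        raise RangeError(spec.item_id, raw, spec.scale_min, spec.scale_max)
    if not (spec.scale_min <= raw <= spec.scale_max):
        raise RangeError(spec.item_id, raw, spec.scale_min, spec.scale_max)
    v = float(raw)
    if spec.inverted:
        v = 10.0 - v
    if spec.doubled:
        v = 2.0 * v
    return v


def resolve_checkbox(raw, ticked: bool):
    """Resolve a work item's scale mark against its "not working" checkbox.

    An existing scale value always wins, even when the box is ticked (double
    entries occur in practice and discarding the mark would force an avoidable
    substitution). A ticked box without a value is a missing value; so is an
    empty field with no tick.
    """
    if not _is_missing(raw):
        return raw
    return MISSING


def _transformed_map(resp: OmpsqResponse, inst: OmpsqInstrument) -> dict[int, Optional[float]]:
    out: dict[int, Optional[float]] = {}
    for spec in inst.items:
        raw = resp.raw_values.get(spec.item_id, MISSING)
        if spec.checkbox_allowed:
            raw = resolve_checkbox(raw, bool(resp.checkbox_ticked.get(spec.item_id, False)))
        elif resp.checkbox_ticked.get(spec.item_id):
            raise InvalidRecordError(
                resp.participant_id, f"checkbox tick on non-checkbox item {spec.item_id}"
            )
        out[spec.item_id] = MISSING if _is_missing(raw) else transform_item(spec, raw)
    return out


def substitute_missing(
    transformed: Mapping[int, Optional[float]], max_substitutions: int = 3
) -> tuple[dict[int, float], int]:
    """Replace missing transformed values by the mean of the answered ones.

    Raises :class:`InvalidRecordError` when more than ``max_substitutions``
    items are missing; record-level callers turn that into an invalid verdict.
    """
    present = {k: v for k, v in transformed.items() if not _is_missing(v)}
    missing = [k for k, v in transformed.items() if _is_missing(v)]
    if len(missing) > max_substitutions:
        raise InvalidRecordError(
            "<record>", f"too many missing: {len(missing)} > {max_substitutions}"
        )
    if not missing:
        return dict(present), 0
    if not present:
        raise InvalidRecordError("<record>", "all items missing")
    m = sum(present.values()) / len(present)
    completed = dict(present)
    for k in missing:
        completed[k] = m
    return completed, len(missing)


def risk_band(total: float, inst: Optional[OmpsqInstrument] = None) -> str:
    """Three-level band on the real-valued total (no rounding before banding)."""
    inst = inst or default_instrument()
    if total < inst.band_low_below:
        return "low"
    if total <= inst.band_high_upto:
        return "medium"
    return "high"


def validate_record(resp: OmpsqResponse, inst: Optional[OmpsqInstrument] = None) -> ValidationResult:
    """Verdict on whether a record can be scored (after checkbox resolution
    and permitted substitution)."""
    inst = inst or default_instrument()
    try:
        transformed = _transformed_map(resp, inst)
    except (RangeError, InvalidRecordError) as exc:
        return ValidationResult(False, str(exc))
    n_missing = sum(1 for v in transformed.values() if _is_missing(v))
    if n_missing > inst.max_substitutions:
        return ValidationResult(False, "too many missing", n_missing)
    if n_missing == len(transformed):
        return ValidationResult(False, "all items missing", n_missing)
    return ValidationResult(True, None, n_missing)


def score_ompsq(resp: OmpsqResponse, inst: Optional[OmpsqInstrument] = None) -> OmpsqScore:
    """Score a validated record; raises :class:`InvalidRecordError` otherwise."""
    inst = inst or default_instrument()
    verdict = validate_record(resp, inst)
    if not verdict:
        raise InvalidRecordError(resp.participant_id, verdict.reason or "invalid")
    transformed = _transformed_map(resp, inst)
    completed, n_sub = substitute_missing(transformed, inst.max_substitutions)
    total = sum(completed.values())
    return OmpsqScore(
        total=total,
        n_substituted=n_sub,
        risk_band=risk_band(total, inst),
        per_item_transformed=completed,
    )
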