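"""Strict CSV readers/writers for baseline and follow-up questionnaire files.

Dialect is fixed: comma separator, dot decimal, UTF-8, header required.
Blank cells and a configurable NA token parse to the explicit MISSING
sentinel; decimal-comma numerals are rejected with a located error rather
than silently coerced (the instruments are German and such files occur).

Baseline schema: ``id``, ``omp_5``..``omp_25``, checkbox booleans
``omp_8_nw``/``omp_16_nw``/``omp_17_nw``, ``hkf_1``..``hkf_27``.
Follow-up schema: ``id``, ``fu_omp_10``, ``fu_omp_11``,
``fu_omp_21``..``fu_omp_25``, ``fu_sickdays``, ``fu_hkf_5``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ParseError
from .hkf import HkfManifest, HkfResponse, default_manifest
from .ompsq import OmpsqInstrument, OmpsqResponse, default_instrument
from .outcomes import FollowUpRecord

__all__ = [
    "BaselineRecord",
    "baseline_columns",
    "followup_columns",
    "read_baseline",
    "write_baseline",
    "read_followup",
    "write_followup",
]

NA_TOKENS = ("", "NA")


@dataclass
class BaselineRecord:
    participant_id: str
    ompsq: OmpsqResponse
    hkf: HkfResponse


def baseline_columns(
    inst: Optional[OmpsqInstrument] = None, manifest: Optional[HkfManifest] = None
) -> list[str]:
    inst = inst or default_instrument()
    manifest = manifest or default_manifest()
    cols = ["id"]
    cols += [f"omp_{i}" for i in inst.item_ids]
    cols += [f"omp_{i}_nw" for i in inst.checkbox_ids]
    cols += [f"hkf_{i}" for i in manifest.item_ids]
    return cols


def followup_columns() -> list[str]:
    return ["id", "fu_omp_10", "fu_omp_11"] + [f"fu_omp_{i}" for i in range(21, 26)] \
        + ["fu_sickdays", "fu_hkf_5"]


def _parse_number(token: str, path, row: int, column: str, na_tokens) -> Optional[float]:
    token = token.strip()
    if token in na_tokens:
        return None
    if "," in token:
        raise ParseError(
            path, f"decimal comma in {token!r}; this reader requires dot decimals",
            row=row, column=column,
        )
    try:
        return float(token)
    except ValueError:
        raise ParseError(path, f"malformed numeric {token!r}", row=row, column=column) from None


def _parse_bool(token: str, path, row: int, column: str) -> bool:
    token = token.strip().lower()
    if token in ("1", "true", "yes"):
        return True
    if token in ("0", "false", "no", ""):
        return False
    raise ParseError(path, f"malformed boolean {token!r}", row=row, column=column)


def _read_rows(path, expected: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, "empty file (header required)") from None
        if set(header) != set(expected):
            unknown = sorted(set(header) - set(expected))
            missing = sorted(set(expected) - set(header))
            raise ParseError(
                path,
                f"schema mismatch: unknown columns {unknown}, missing columns {missing}",
            )
        rows = []
        for idx, values in enumerate(reader, start=2):
            if len(values) != len(header):
                raise ParseError(path, f"expected {len(header)} fields, got {len(values)}", row=idx)
            rows.append(dict(zip(header, values)))
    return rows


def _check_unique_ids(records, path):
    seen = set()
    for rec in records:
        pid = rec[0]
        if pid in seen:
            raise ParseError(path, f"duplicate participant id {pid!r}")
        seen.add(pid)


def read_baseline(
    path,
    inst: Optional[OmpsqInstrument] = None,
    manifest: Optional[HkfManifest] = None,
    na_tokens: Sequence[str] = NA_TOKENS,
) -> list[BaselineRecord]:
    inst = inst or default_instrument()
    manifest = manifest or default_manifest()
    rows = _read_rows(path, baseline_columns(inst, manifest))
    out: list[BaselineRecord] = []
    for idx, row in enumerate(rows, start=2):
        pid = row["id"].strip()
        if not pid:
            raise ParseError(path, "empty participant id", row=idx, column="id")
        raw = {
            i: _parse_number(row[f"omp_{i}"], path, idx, f"omp_{i}", na_tokens)
            for i in inst.item_ids
        }
        ticked = {
            i: _parse_bool(row[f"omp_{i}_nw"], path, idx, f"omp_{i}_nw")
            for i in inst.checkbox_ids
        }
        hkf_vals = {
            i: _parse_number(row[f"hkf_{i}"], path, idx, f"hkf_{i}", na_tokens)
            for i in manifest.item_ids
        }
        out.append(
            BaselineRecord(
                participant_id=pid,
                ompsq=OmpsqResponse(pid, raw_values=raw, checkbox_ticked=ticked),
                hkf=HkfResponse(pid, item_values=hkf_vals),
            )
        )
    _check_unique_ids([(r.participant_id,) for r in out], path)
    return out


def _fmt(v) -> str:
    if v is None:
        return ""
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def write_baseline(
    records: Sequence[BaselineRecord],
    path,
    inst: Optional[OmpsqInstrument] = None,
    manifest: Optional[HkfManifest] = None,
) -> None:
    inst = inst or default_instrument()
    manifest = manifest or default_manifest()
    cols = baseline_columns(inst, manifest)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            row = [rec.participant_id]
            row += [_fmt(rec.ompsq.raw_values.get(i)) for i in inst.item_ids]
            row += ["1" if rec.ompsq.checkbox_ticked.get(i) else "0" for i in inst.checkbox_ids]
            row += [_fmt(rec.hkf.item_values.get(i)) for i in manifest.item_ids]
            writer.writerow(row)


def read_followup(path, na_tokens: Sequence[str] = NA_TOKENS) -> list[FollowUpRecord]:
    rows = _read_rows(path, followup_columns())
    out: list[FollowUpRecord] = []
    for idx, row in enumerate(rows, start=2):
        pid = row["id"].strip()
        if not pid:
            raise ParseError(path, "empty participant id", row=idx, column="id")
        days = _parse_number(row["fu_sickdays"], path, idx, "fu_sickdays", na_tokens)
        if days is not None:
            if days != int(days) or days < 0:
                raise ParseError(
                    path, f"sick-leave days must be a non-negative integer, got {days}",
                    row=idx, column="fu_sickdays",
                )
            days = int(days)
        func = [
            _parse_number(row[f"fu_omp_{i}"], path, idx, f"fu_omp_{i}", na_tokens)
            for i in range(21, 26)
        ]
        out.append(
            FollowUpRecord(
                participant_id=pid,
                pain_intensity=_parse_number(row["fu_omp_10"], path, idx, "fu_omp_10", na_tokens),
                pain_frequency=_parse_number(row["fu_omp_11"], path, idx, "fu_omp_11", na_tokens),
                function_items=func,
                sick_leave_days=days,
                hkf_pain_vas=_parse_number(row["fu_hkf_5"], path, idx, "fu_hkf_5", na_tokens),
            )
        )
    _check_unique_ids([(r.participant_id,) for r in out], path)
    return out


def write_followup(records: Sequence[FollowUpRecord], path) -> None:
    cols = followup_columns()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            func = rec.function_items or [None] * 5
            row = [rec.participant_id, _fmt(rec.pain_intensity), _fmt(rec.pain_frequency)]
            row += [_fmt(v) for v in func]
            row += [_fmt(rec.sick_leave_days), _fmt(rec.hkf_pain_vas)]
            writer.writerow(row)
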