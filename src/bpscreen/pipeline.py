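"""End-to-end study orchestration: read → validate → score → label → report.

:func:`run_study` composes the scoring, outcome and validity modules into the
study's analysis flow and returns a :class:`StudyReport` whose tables mirror
the published report structure: a sample-flow account of every exclusion
step, a per-outcome AUC block (counts, prevalence, AUC, SE, p, CI), a
per-outcome cut-off table (Youden-optimal row plus requested cut-off rows,
each with sample-prevalence and population-prevalence predictive values and
test-efficiency bands), and the preliminary ANOVA.

:func:`report_from_matrices` is a matrix-injection entry point: it accepts
printed confusion matrices directly, so published validity tables can be
recomputed and checked without any raw scores.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .compare import AnovaResult, oneway_anova
from .errors import DegenerateDataError
from .hkf import default_manifest, load_weights, score_hkf, validate_hkf
from .io import read_baseline, read_followup
from .ompsq import load_instrument, default_instrument, score_ompsq, validate_record
from .outcomes import OUTCOMES, Subsample, build_subsamples, label_followup
from .validity import (
    ConfusionMatrix,
    RocCurve,
    classify_nlr,
    classify_plr,
    classify_quality,
    classify_quality_sum,
    adjust_pv,
    confusion_at_cutoff,
    metrics,
    roc_coordinates,
    youden_optimal,
)

__all__ = ["RunConfig", "StudyReport", "run_study", "report_from_matrices", "rebuild_report"]

log = logging.getLogger("bpscreen.pipeline")


def _default_report_cutoffs() -> dict[str, list[float]]:
    # published example rows: a balanced-proportion cut-off and a
    # sensitivity>=80% cut-off per instrument
    return {
        "ompsq_pain": [84.0, 76.0],
        "ompsq_sickleave": [84.0, 76.0],
        "ompsq_function": [84.0, 76.0],
        "hkf_pain": [37.0, 20.0],
    }


@dataclass
class RunConfig:
    baseline_path: str
    followup_path: str
    item_spec_path: Optional[str] = None
    weight_spec_path: Optional[str] = None
    population_prevalence: float = 0.10
    report_cutoffs: dict[str, list[float]] = field(default_factory=_default_report_cutoffs)
    out_dir: Optional[str] = None
    positive_ge: bool = True

    def __post_init__(self):
        if not (0.0 < self.population_prevalence < 1.0):
            raise ValueError("population_prevalence must lie in (0, 1)")


@dataclass
class StudyReport:
    sample_flow: pd.DataFrame
    anova: pd.DataFrame
    auc_table: pd.DataFrame
    cutoff_table: pd.DataFrame
    subsamples: dict[str, Subsample]
    curves: dict[str, RocCurve]


def _cutoff_row(
    outcome: str,
    cm: ConfusionMatrix,
    cutoff: float,
    population_prevalence: float,
    is_youden: bool,
) -> dict:
    m = metrics(cm, cutoff=cutoff)
    adj = adjust_pv(m.plr, m.nlr, population_prevalence)
    return {
        "outcome": outcome,
        "cutoff": cutoff,
        "youden_optimal": is_youden,
        "prevalence": m.prevalence,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "youden_j": m.youden_j,
        "plr": m.plr,
        "nlr": m.nlr,
        "ppv": m.ppv,
        "npv": m.npv,
        "accuracy": m.accuracy,
        "adj_prevalence": population_prevalence,
        "adj_ppv": adj.ppv,
        "adj_npv": adj.npv,
        "plr_band": classify_plr(m.plr),
        "nlr_band": classify_nlr(m.nlr),
        "sens_spec_sum_band": classify_quality_sum(100.0 * (m.sensitivity + m.specificity)),
        "tn": cm.tn,
        "fp": cm.fp,
        "tp": cm.tp,
        "fn": cm.fn,
    }


def _analyze_subsamples(
    subsamples: Mapping[str, Subsample],
    report_cutoffs: Mapping[str, list[float]],
    population_prevalence: float,
    positive_ge: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, RocCurve]]:
    auc_rows, cut_rows, anova_rows = [], [], []
    curves: dict[str, RocCurve] = {}
    for outcome in OUTCOMES:
        sub = subsamples.get(outcome)
        if sub is None or sub.n == 0:
            log.warning("outcome %s skipped: empty sub-sample", outcome)
            continue
        try:
            curve = roc_coordinates(sub.scores, sub.diseased, positive_ge)
        except DegenerateDataError as exc:
            log.warning("outcome %s skipped: %s", outcome, exc)
            continue
        curves[outcome] = curve
        auc_rows.append(
            {
                "outcome": outcome,
                "n": sub.n,
                "tn": 0,
                "fp": 0,
                "tp": 0,
                "fn": 0,
                "prevalence": sub.prevalence,
                "auc": curve.auc,
                "se": curve.se,
                "p_vs_half": curve.p_vs_half,
                "ci_lower": curve.ci95[0],
                "ci_upper": curve.ci95[1],
                "auc_quality": classify_quality(100.0 * curve.auc),
            }
        )
        best = youden_optimal(curve)
        cm_best = confusion_at_cutoff(sub.scores, sub.diseased, best.cutoff, positive_ge)
        cut_rows.append(
            _cutoff_row(outcome, cm_best, best.cutoff, population_prevalence, True)
        )
        # fold the Youden matrix counts into the AUC table (report convention)
        auc_rows[-1].update({"tn": cm_best.tn, "fp": cm_best.fp, "tp": cm_best.tp, "fn": cm_best.fn})
        for c in report_cutoffs.get(outcome, []):
            cm_c = confusion_at_cutoff(sub.scores, sub.diseased, c, positive_ge)
            cut_rows.append(_cutoff_row(outcome, cm_c, c, population_prevalence, False))
        # preliminary ANOVA: baseline scores across recovered / not recovered
        groups = {
            "not_recovered": sub.scores[sub.diseased],
            "recovered": sub.scores[~sub.diseased],
        }
        try:
            res: AnovaResult = oneway_anova(groups)
            anova_rows.append(
                {
                    "outcome": outcome,
                    "f": res.f,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p": res.p,
                }
            )
        except DegenerateDataError as exc:
            log.warning("ANOVA for %s skipped: %s", outcome, exc)
    return (
        pd.DataFrame(auc_rows),
        pd.DataFrame(cut_rows),
        pd.DataFrame(anova_rows),
        curves,
    )


def run_study(cfg: RunConfig) -> StudyReport:
    inst = load_instrument(cfg.item_spec_path) if cfg.item_spec_path else default_instrument()
    manifest = default_manifest()
    weights = load_weights(cfg.weight_spec_path)

    records = read_baseline(cfg.baseline_path, inst, manifest)
    n_baseline = len(records)
    log.info("step=read_baseline in=%s out=%s", cfg.baseline_path, n_baseline)

    ompsq_totals, hkf_scores = [], []
    n_omp_invalid = n_hkf_invalid = 0
    n_substituted_records = 0
    for rec in records:
        if validate_record(rec.ompsq, inst):
            score = score_ompsq(rec.ompsq, inst)
            ompsq_totals.append((rec.participant_id, score.total))
            if score.n_substituted:
                n_substituted_records += 1
        else:
            n_omp_invalid += 1
        if validate_hkf(rec.hkf, manifest):
            hkf_scores.append((rec.participant_id, score_hkf(rec.hkf, weights, manifest).score))
        else:
            n_hkf_invalid += 1
    log.info(
        "step=score ompsq_valid=%d ompsq_invalid=%d hkf_valid=%d hkf_invalid=%d substituted=%d",
        len(ompsq_totals), n_omp_invalid, len(hkf_scores), n_hkf_invalid, n_substituted_records,
    )

    fu_records = read_followup(cfg.followup_path)
    labels = {r.participant_id: label_followup(r) for r in fu_records}
    log.info("step=read_followup returned=%d", len(fu_records))

    subsamples = build_subsamples(ompsq_totals, hkf_scores, labels)
    flow_rows = [
        {"step": "baseline_records", "count": n_baseline},
        {"step": "ompsq_valid", "count": len(ompsq_totals)},
        {"step": "ompsq_invalid", "count": n_omp_invalid},
        {"step": "ompsq_substituted_records", "count": n_substituted_records},
        {"step": "hkf_valid", "count": len(hkf_scores)},
        {"step": "hkf_invalid", "count": n_hkf_invalid},
        {"step": "followup_returned", "count": len(fu_records)},
    ]
    for outcome in OUTCOMES:
        n_labeled = sum(1 for labs in labels.values() if outcome in labs)
        flow_rows.append({"step": f"labeled_{outcome}", "count": n_labeled})
        flow_rows.append({"step": f"subsample_{outcome}", "count": subsamples[outcome].n})
    sample_flow = pd.DataFrame(flow_rows)

    auc_table, cutoff_table, anova, curves = _analyze_subsamples(
        subsamples, cfg.report_cutoffs, cfg.population_prevalence, cfg.positive_ge
    )
    report = StudyReport(
        sample_flow=sample_flow,
        anova=anova,
        auc_table=auc_table,
        cutoff_table=cutoff_table,
        subsamples=subsamples,
        curves=curves,
    )
    if cfg.out_dir:
        _write_artifacts(report, cfg)
    return report


def _write_artifacts(report: StudyReport, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.sample_flow.to_csv(out / "sample_flow.tsv", sep="\t", index=False)
    report.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    report.auc_table.to_csv(out / "auc_table.tsv", sep="\t", index=False)
    report.cutoff_table.to_csv(out / "cutoff_table.tsv", sep="\t", index=False)
    for outcome, curve in report.curves.items():
        coords = pd.DataFrame(
            [
                {
                    "cutoff": p.cutoff, "sens": p.sensitivity, "spec": p.specificity,
                    "J": p.youden_j, "PLR": p.plr, "NLR": p.nlr, "PPV": p.ppv,
                    "NPV": p.npv, "ACC": p.accuracy,
                }
                for p in curve.points
            ]
        )
        coords.to_csv(out / f"coordinates_{outcome}.tsv", sep="\t", index=False)
    for outcome, sub in report.subsamples.items():
        pd.DataFrame(
            {"id": sub.ids, "score": sub.scores, "diseased": sub.diseased.astype(int)}
        ).to_csv(out / f"subsample_{outcome}.csv", index=False)
    meta = {
        "population_prevalence": cfg.population_prevalence,
        "report_cutoffs": cfg.report_cutoffs,
        "positive_ge": cfg.positive_ge,
    }
    (out / "run_config.json").write_text(json.dumps(meta, indent=2))
    log.info("step=write_artifacts out=%s", out)


def rebuild_report(archive_dir) -> StudyReport:
    """Re-render validity tables from archived sub-samples (no raw scores needed)."""
    out = Path(archive_dir)
    meta = json.loads((out / "run_config.json").read_text())
    subsamples: dict[str, Subsample] = {}
    for outcome in OUTCOMES:
        f = out / f"subsample_{outcome}.csv"
        if not f.exists():
            continue
        df = pd.read_csv(f, dtype={"id": str})
        subsamples[outcome] = Subsample(
            outcome=outcome,
            ids=list(df["id"]),
            scores=df["score"].to_numpy(float),
            diseased=df["diseased"].to_numpy(bool),
        )
    auc_table, cutoff_table, anova, curves = _analyze_subsamples(
        subsamples,
        {k: list(v) for k, v in meta["report_cutoffs"].items()},
        meta["population_prevalence"],
        meta.get("positive_ge", True),
    )
    flow = pd.DataFrame(
        [{"step": f"subsample_{o}", "count": s.n} for o, s in subsamples.items()]
    )
    return StudyReport(
        sample_flow=flow, anova=anova, auc_table=auc_table,
        cutoff_table=cutoff_table, subsamples=subsamples, curves=curves,
    )


def report_from_matrices(
    matrices: Mapping[str, ConfusionMatrix],
    population_prevalence: float = 0.10,
    cutoffs: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Validity parameters straight from printed confusion matrices.

    One row per entry with the full cut-off-associated bundle plus
    population-prevalence-adjusted predictive values; used to recompute
    published tables when raw scores are unavailable.
    """
    rows = []
    for outcome, cm in matrices.items():
        c = float(cutoffs[outcome]) if cutoffs and outcome in cutoffs else math.nan
        rows.append(_cutoff_row(outcome, cm, c, population_prevalence, True))
    return pd.DataFrame(rows)
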