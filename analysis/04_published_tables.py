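"""Recompute the published validity tables from their printed counts.

The study's raw scores were never deposited, but its per-outcome confusion
matrices at the Youden-optimal cut-offs are printed. Injecting them into
the metric engine reproduces the cut-off-associated validity parameters
(sensitivity, specificity, PLR, NLR, PPV, NPV, accuracy) and the
predictive values re-calculated at the 10% German population prevalence,
along with the test-efficiency classifications. Writes
results/published_tables_recomputed.tsv.
"""

from pathlib import Path

from bpscreen.pipeline import report_from_matrices
from bpscreen.validity import ConfusionMatrix, adjust_pv

RESULTS = Path(__file__).resolve().parents[1] / "results"

MATRICES = {
    "ompsq_pain": ConfusionMatrix(tp=44, fp=15, tn=46, fn=17),
    "ompsq_sickleave": ConfusionMatrix(tp=25, fp=10, tn=58, fn=15),
    "ompsq_function": ConfusionMatrix(tp=62, fp=25, tn=33, fn=2),
    "hkf_pain": ConfusionMatrix(tp=45, fp=6, tn=32, fn=45),
}


def main() -> None:
    df = report_from_matrices(MATRICES, population_prevalence=0.10)
    out = RESULTS / "published_tables_recomputed.tsv"
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    cols = ["outcome", "prevalence", "sensitivity", "specificity", "plr", "nlr",
            "ppv", "npv", "accuracy", "adj_ppv", "adj_npv", "plr_band", "nlr_band"]
    print(df[cols].round(3).to_string(index=False))
    print("\nworked predictive-value grid (PPV/NPV in % by prevalence):")
    for label, sens in (("very high efficiency (sens=spec=0.95)", 0.95),
                        ("moderate efficiency  (sens=spec=0.70)", 0.70)):
        plr, nlr = sens / (1 - sens), (1 - sens) / sens
        cells = []
        for prev in (0.90, 0.50, 0.10, 0.01):
            adj = adjust_pv(plr, nlr, prev)
            cells.append(f"{prev:>4.0%}: {100 * adj.ppv:5.1f}/{100 * adj.npv:5.1f}")
        print(f"  {label}  " + "  ".join(cells))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
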