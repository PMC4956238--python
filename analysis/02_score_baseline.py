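"""Score the baseline questionnaires and account for every exclusion.

Applies the full ÖMPSQ rule set (checkbox resolution, reverse-coding,
doubling, mean substitution up to 3 items) and the HKF-R 10 weighted
sum-product score with its strict no-missing policy, then tabulates risk
bands / categories. Writes results/scored_baseline.csv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from bpscreen.hkf import default_manifest, load_weights, score_hkf, validate_hkf
from bpscreen.io import read_baseline
from bpscreen.ompsq import default_instrument, score_ompsq, validate_record

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_baseline(RESULTS / "cohort" / "baseline.csv")
    inst, manifest, weights = default_instrument(), default_manifest(), load_weights()
    rows, bands, cats = [], Counter(), Counter()
    n_omp_invalid = n_hkf_invalid = n_substituted = 0
    for rec in records:
        row = {"id": rec.participant_id}
        if validate_record(rec.ompsq, inst):
            s = score_ompsq(rec.ompsq, inst)
            row.update(ompsq_total=s.total, ompsq_band=s.risk_band,
                       ompsq_substituted=s.n_substituted)
            bands[s.risk_band] += 1
            n_substituted += s.n_substituted > 0
        else:
            n_omp_invalid += 1
        if validate_hkf(rec.hkf, manifest):
            h = score_hkf(rec.hkf, weights, manifest)
            row.update(hkf_score=h.score, hkf_category=h.category)
            cats[h.category] += 1
        else:
            n_hkf_invalid += 1
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "scored_baseline.csv", index=False)
    n = len(records)
    print(f"scored {n} baselines -> {RESULTS / 'scored_baseline.csv'}")
    print(f"  OMPSQ valid {n - n_omp_invalid}, invalid {n_omp_invalid}, "
          f"mean-substituted records {n_substituted}")
    print(f"  OMPSQ risk bands: {dict(bands)}")
    print(f"  HKF valid {n - n_hkf_invalid}, invalid {n_hkf_invalid} "
          f"(synthetic placeholder weights)")
    print(f"  HKF categories: {dict(cats)}")


if __name__ == "__main__":
    main()
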