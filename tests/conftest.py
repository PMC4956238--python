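import numpy as np
import pytest

from bpscreen.ompsq import OmpsqResponse, default_instrument
from bpscreen.validity import ConfusionMatrix

# Published per-outcome confusion matrices at the Youden-optimal cut-offs
# (TN, FP, TP, FN order as printed) and the metric values printed next to them.
PUBLISHED_MATRICES = {
    "ompsq_pain": ConfusionMatrix(tp=44, fp=15, tn=46, fn=17),
    "ompsq_sickleave": ConfusionMatrix(tp=25, fp=10, tn=58, fn=15),
    "ompsq_function": ConfusionMatrix(tp=62, fp=25, tn=33, fn=2),
    "hkf_pain": ConfusionMatrix(tp=45, fp=6, tn=32, fn=45),
}

PUBLISHED_METRICS = {
    # sens, spec, PLR, NLR, PPV, NPV, ACC as printed (2 dp)
    "ompsq_pain": (0.72, 0.75, 2.93, 0.37, 0.75, 0.73, 0.74),
    "ompsq_sickleave": (0.63, 0.85, 4.25, 0.44, 0.71, 0.80, 0.77),
    "ompsq_function": (0.97, 0.57, 2.25, 0.06, 0.71, 0.94, 0.78),
    "hkf_pain": (0.50, 0.84, 3.17, 0.59, 0.88, 0.42, 0.60),
}

# re-calculated predictive values at 10% population prevalence, as printed
PUBLISHED_ADJUSTED_PV = {
    "ompsq_pain": (0.25, 0.96),
    "ompsq_sickleave": (0.32, 0.95),
    "ompsq_function": (0.20, 0.99),
    "hkf_pain": (0.26, 0.94),
}


@pytest.fixture
def instrument():
    return default_instrument()


def make_response(overrides=None, ticked=None, pid="P1"):
    """A complete mid-scale response; override single items as needed."""
    inst = default_instrument()
    raw = {}
    for spec in inst.items:
        raw[spec.item_id] = max(spec.scale_min, min(5, spec.scale_max))
    if overrides:
        raw.update(overrides)
    return OmpsqResponse(pid, raw_values=raw, checkbox_ticked=dict(ticked or {}))


def minimal_response():
    """Raw values minimizing the transformed total (total = 4)."""
    inst = default_instrument()
    raw = {}
    for spec in inst.items:
        raw[spec.item_id] = spec.scale_max if spec.inverted else spec.scale_min
    return OmpsqResponse("MIN", raw_values=raw)


def maximal_response():
    inst = default_instrument()
    raw = {}
    for spec in inst.items:
        raw[spec.item_id] = spec.scale_min if spec.inverted else spec.scale_max
    return OmpsqResponse("MAX", raw_values=raw)


def pairwise_auc(scores, diseased):
    """O(n^2) Mann-Whitney oracle: wins + half-ties over all D/N pairs."""
    scores = np.asarray(scores, float)
    diseased = np.asarray(diseased, bool)
    sd, sn = scores[diseased], scores[~diseased]
    wins = ties = 0
    for a in sd:
        for b in sn:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(sd) * len(sn))


def brute_confusion(scores, diseased, cutoff):
    tp = fp = tn = fn = 0
    for s, d in zip(scores, diseased):
        pos = s >= cutoff
        if pos and d:
            tp += 1
        elif pos and not d:
            fp += 1
        elif not pos and d:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
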