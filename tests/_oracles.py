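"""Independent brute-force oracles used to cross-check the evaluation code.

These are deliberately written from the definitions, without reference to
the package implementation or to scikit-learn.
"""

import numpy as np


def oracle_metrics(tp, tn, fp, fn):
    """Confusion metrics straight from the definitions."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    mcc = (tp * tn - fp * fn) / den if den > 0 else 0.0
    return acc, sn, sp, mcc


def oracle_auc_all_pairs(y, s):
    """Mann-Whitney: P(random positive outscores random negative), ties 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def oracle_average_precision(y, s):
    """AUPRC by exhaustive threshold enumeration (step/AP convention)."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    thresholds = np.unique(s)[::-1]
    n_pos = int(y.sum())
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        calls = s >= t
        tp = int(np.sum(calls & (y == 1)))
        precision = tp / int(calls.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
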