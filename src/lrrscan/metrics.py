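"""Confusion-matrix metrics and unit-level benchmarking of interval calls.

Sensitivity, precision, F1 and the Matthews correlation coefficient are
computed from TP/TN/FP/FN counts; any zero denominator returns 0 by
convention.  For interval-level benchmarking, predicted and true units are
matched one-to-one, greedily by overlap size, a pair counting as a match
when the reciprocal overlap (relative to both intervals) reaches the match
threshold (default 50%).  True negatives are undefined at unit level and
reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .caller import LRRUnitCall


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def sensitivity(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def f1(c: ConfusionCounts) -> float:
    pre, sen = precision(c), sensitivity(c)
    return 2 * pre * sen / (pre + sen) if pre + sen else 0.0


def mcc(c: ConfusionCounts) -> float:
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return (c.tp * c.tn - c.fp * c.fn) / denom if denom else 0.0


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "sensitivity": sensitivity(c),
        "precision": precision(c),
        "f1": f1(c),
        "mcc": mcc(c),
    }


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def confusion_from_calls(
    predicted: list[tuple[int, int]] | list[LRRUnitCall],
    truth: list[tuple[int, int]],
    min_reciprocal_overlap: float = 0.5,
) -> ConfusionCounts:
    """Unit-level counts from interval calls (1-based inclusive intervals).

    A predicted unit is a TP when matched one-to-one to a true unit with
    overlap >= ``min_reciprocal_overlap`` of BOTH interval lengths; matching
    is greedy by decreasing overlap.  Unmatched predictions are FP and
    unmatched true units FN; TN is reported as 0.
    """
    pred = [
        (u.start, u.end) if isinstance(u, LRRUnitCall) else tuple(u)
        for u in predicted
    ]
    pairs = []
    for i, p in enumerate(pred):
        lp = p[1] - p[0] + 1
        for j, t in enumerate(truth):
            lt = t[1] - t[0] + 1
            ov = _overlap(p, t)
            if ov >= min_reciprocal_overlap * lp and ov >= min_reciprocal_overlap * lt:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_pred or j in used_truth:
            continue
        used_pred.add(i)
        used_truth.add(j)
        tp += 1
    return ConfusionCounts(
        tp=tp, tn=0, fp=len(pred) - tp, fn=len(truth) - tp
    )


def evaluate_peptide_classifier(
    model, records, threshold: float = 0.5
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Threshold LPS scores of labeled UnitRecords and compute all metrics."""
    scores = model.score_sequences([r.sequence for r in records])
    y = np.array([r.label == "positive" for r in records])
    pred = scores >= threshold
    counts = ConfusionCounts(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )
    return counts, all_metrics(counts)
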