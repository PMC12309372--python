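"""Interval-level scoring of predictions against truth annotations."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .core_io import GenomicInterval

__all__ = [
    "MatchResult",
    "match_predictions",
    "precision",
    "recall",
    "f1",
    "accuracy",
]

logger = logging.getLogger(__name__)

#: A truth locus counts as recovered when a same-strand prediction
#: overlaps at least this fraction of the truth length.
MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]  # (prediction index, truth index)


def match_predictions(predictions: Sequence[GenomicInterval],
                      truth: Sequence[GenomicInterval],
                      strand_aware: bool = True,
                      min_overlap_fraction: float = MIN_OVERLAP_FRACTION,
                      ) -> MatchResult:
    """Greedy one-to-one matching by descending overlap.

    A (prediction, truth) pair is eligible when they overlap by at least
    ``min_overlap_fraction`` of the truth length (and share a strand when
    ``strand_aware``). Eligible pairs are consumed in order of decreasing
    overlap; matched truths are TP, unmatched predictions FP, unmatched
    truths FN.
    """
    candidates = []
    for pi, pred in enumerate(predictions):
        for ti, t in enumerate(truth):
            if strand_aware and pred.strand != t.strand:
                continue
            ov = pred.overlap(t)
            if ov >= min_overlap_fraction * t.length:
                candidates.append((ov, pi, ti))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    pairs = []
    for ov, pi, ti in candidates:
        if pi in used_pred or ti in used_truth:
            continue
        used_pred.add(pi)
        used_truth.add(ti)
        pairs.append((pi, ti))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(predictions) - tp,
        fn=len(truth) - tp,
        pairs=tuple(sorted(pairs)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", name)
        return 0.0
    return num / den


def precision(tp: int, fp: int) -> float:
    return _ratio(tp, tp + fp, "precision")


def recall(tp: int, fn: int) -> float:
    return _ratio(tp, tp + fn, "recall")


def f1(p: float, r: float) -> float:
    return _ratio(2 * p * r, p + r, "F1")


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    return _ratio(tp + tn, tp + tn + fp + fn, "accuracy")
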