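"""Three-filter merging of raw window predictions into candidate loci.

The filters run in order: (i) keep windows with probability >= p1,
(ii) merge maximal runs of consecutive positive windows and keep runs of
at least w windows, (iii) return the center window of each run if it is
itself predicted positively. "Consecutive" means successive starts differ
by exactly the scan step size; any gap breaks a block. Blocks never span
chromosomes or strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core_io import GenomicInterval, WindowPrediction
from .scanner import WindowClassifier, extract_window_seq

__all__ = [
    "MergeConfig",
    "CandidateBlock",
    "filter_positive",
    "merge_blocks",
    "select_center",
    "merge_predictions",
]

logger = logging.getLogger(__name__)

#: Default probability threshold for whole-genome (FASTA) input.
DEFAULT_P1_FASTA = 0.999
#: Relaxed threshold for targeted BED-region input.
DEFAULT_P1_BED = 0.9
#: Minimum number of consecutive positive windows per block.
DEFAULT_MIN_WINDOWS = 10


@dataclass(frozen=True)
class MergeConfig:
    p1: float = DEFAULT_P1_FASTA
    min_windows: int = DEFAULT_MIN_WINDOWS

    def __post_init__(self) -> None:
        if not (0.0 < self.p1 <= 1.0):
            raise ValueError("p1 must be in (0, 1]")
        if self.min_windows < 1:
            raise ValueError("min_windows must be >= 1")


@dataclass(frozen=True)
class CandidateBlock:
    """A maximal run of consecutive positive windows on one strand."""

    members: tuple[WindowPrediction, ...]

    @property
    def center(self) -> WindowPrediction:
        """The lower-median member (deterministic tie-break for even runs)."""
        return self.members[(len(self.members) - 1) // 2]


def filter_positive(predictions: Sequence[WindowPrediction],
                    p1: float) -> list[WindowPrediction]:
    """Keep windows with probability >= p1 (boundary inclusive)."""
    return [p for p in predictions if p.probability >= p1]


def merge_blocks(positives: Sequence[WindowPrediction], step_size: int,
                 min_windows: int) -> list[CandidateBlock]:
    """Group positives into maximal consecutive runs; drop runs < min_windows.

    Input may be unsorted; it is grouped by (chrom, strand) and sorted by
    start internally. Successive members of a block differ in start by
    exactly ``step_size``.
    """
    by_group: dict[tuple[str, str], list[WindowPrediction]] = {}
    for p in positives:
        key = (p.interval.chrom, p.interval.strand or ".")
        by_group.setdefault(key, []).append(p)
    blocks: list[CandidateBlock] = []
    for key in sorted(by_group):
        group = sorted(by_group[key], key=lambda p: p.interval.start)
        run: list[WindowPrediction] = []
        for p in group:
            if run and p.interval.start - run[-1].interval.start != step_size:
                if len(run) >= min_windows:
                    blocks.append(CandidateBlock(tuple(run)))
                run = []
            run.append(p)
        if len(run) >= min_windows:
            blocks.append(CandidateBlock(tuple(run)))
    return blocks


def select_center(block: CandidateBlock, classifier: WindowClassifier,
                  genome: Mapping[str, str], p1: float,
                  rescue_best_window: bool = False,
                  ) -> Optional[WindowPrediction]:
    """Re-score the block's center window; keep the block only if positive.

    Returns the center window (with its freshly computed probability) when
    it scores >= p1, otherwise ``None`` and the block is logged as dropped.
    With ``rescue_best_window`` the highest-probability member is returned
    instead of discarding (off by default).
    """
    center = block.center
    seq = extract_window_seq(genome, center.interval)
    prob = float(classifier.predict([seq])[0])
    if prob >= p1:
        return WindowPrediction(center.interval, prob)
    iv = center.interval
    logger.info(
        "dropping block at %s:%d-%d(%s): center probability %.4g < p1=%g",
        iv.chrom, iv.start, iv.end, iv.strand, prob, p1,
    )
    if rescue_best_window:
        return max(block.members, key=lambda p: p.probability)
    return None


def merge_predictions(predictions: Sequence[WindowPrediction],
                      classifier: WindowClassifier,
                      genome: Mapping[str, str],
                      step_size: int,
                      config: MergeConfig = MergeConfig(),
                      rescue_best_window: bool = False,
                      ) -> list[WindowPrediction]:
    """Run the full three-filter strategy; returns one window per candidate."""
    positives = filter_positive(predictions, config.p1)
    blocks = merge_blocks(positives, step_size, config.min_windows)
    centers = []
    for block in blocks:
        center = select_center(block, classifier, genome, config.p1,
                               rescue_best_window=rescue_best_window)
        if center is not None:
            centers.append(center)
    return centers
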