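"""Coverage-based validation of predictions against read-depth tracks.

A prediction passes when (1) reads on its strand cover at least 50% of
its length, (2) its mean depth exceeds 5 reads, and (3) neither 20 nt
flank carries more than a third of the prediction's mean depth. The
flank rule is applied to each flank individually (the stricter reading)
and the one-third bound is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import EXPRESSED, PSEUDOGENE, CoverageTrack, GenomicInterval

__all__ = [
    "coverage_fraction",
    "mean_depth",
    "passes_expression_filters",
    "label_expressed_by_tpm",
    "FilterResult",
    "MIN_COVERAGE_FRACTION",
    "MIN_MEAN_DEPTH",
    "DEFAULT_FLANK",
]

MIN_COVERAGE_FRACTION = 0.5
MIN_MEAN_DEPTH = 5.0
DEFAULT_FLANK = 20
TPM_THRESHOLD = 1.0


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str  # "" when passed; else first violated criterion


def _strand(locus: GenomicInterval) -> str:
    if locus.strand not in ("+", "-"):
        raise ValueError("locus must be stranded for coverage validation")
    return locus.strand


def coverage_fraction(locus: GenomicInterval, track: CoverageTrack) -> float:
    """Fraction of locus positions with same-strand depth > 0."""
    depth = track.depth(locus.chrom, _strand(locus), locus.start, locus.end)
    return float(np.mean(depth > 0))


def mean_depth(interval: GenomicInterval, track: CoverageTrack) -> float:
    """Mean per-base depth over the interval; absent positions count as 0."""
    depth = track.depth(interval.chrom, _strand(interval),
                        interval.start, interval.end)
    return float(depth.mean())


def passes_expression_filters(locus: GenomicInterval, track: CoverageTrack,
                              flank: int = DEFAULT_FLANK) -> FilterResult:
    """Apply the three read-support criteria; name the first violated one.

    Flanks are clipped at position 0 (chromosome start); a clipped-away
    flank imposes no constraint.
    """
    if coverage_fraction(locus, track) < MIN_COVERAGE_FRACTION:
        return FilterResult(False, "coverage_fraction")
    locus_mean = mean_depth(locus, track)
    if not locus_mean > MIN_MEAN_DEPTH:
        return FilterResult(False, "mean_depth")
    flank_bound = locus_mean / 3.0
    left_lo = max(0, locus.start - flank)
    if left_lo < locus.start:
        left = GenomicInterval(locus.chrom, left_lo, locus.start, locus.strand)
        if mean_depth(left, track) > flank_bound:
            return FilterResult(False, "flank")
    right = GenomicInterval(locus.chrom, locus.end, locus.end + flank, locus.strand)
    if mean_depth(right, track) > flank_bound:
        return FilterResult(False, "flank")
    return FilterResult(True, "")


def label_expressed_by_tpm(abundance_by_condition: Sequence[float]) -> str:
    """Expressed when any per-condition mean abundance exceeds 1 TPM."""
    if len(abundance_by_condition) == 0:
        raise ValueError("no conditions provided")
    if any(a > TPM_THRESHOLD for a in abundance_by_condition):
        return EXPRESSED
    return PSEUDOGENE
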