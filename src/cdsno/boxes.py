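"""Box-motif annotation of positive windows.

A per-nucleotide importance profile is derived from the window classifier
by occlusion: every 6 nt span of the window is masked with N and the drop
in positive probability is averaged over the spans covering each
nucleotide. Peaks of the smoothed profile localize the candidate motifs;
the C (RTGATGA) and D (CTGA) boxes are chosen as the pair minimizing the
total Hamming distance to consensus, with C restricted to the first half
of the window and D to the second half. The internal D' and C' boxes are
then found by exhaustive minimal-Hamming search between C and D. SnoRNA
boundaries are the fifth nucleotide upstream of the C box and the fifth
nucleotide downstream of the D box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core_io import GenomicInterval
from .features import C_CONSENSUS, D_CONSENSUS, box_hamming
from .scanner import WindowClassifier

__all__ = [
    "Box",
    "BoxAnnotation",
    "compute_importance",
    "detect_peaks",
    "find_cd_pair",
    "find_prime_boxes",
    "define_boundaries",
    "annotate_window",
    "BOUNDARY_OFFSET",
]

logger = logging.getLogger(__name__)

#: Span length used for occlusion masking (matches k-mer width).
OCCLUSION_SPAN = 6
#: A motif start is eligible when within this distance of a profile peak.
#: Occlusion spans (6 nt) spread a motif's importance up to span - 1 nt
#: downstream and the smoothing filter shifts apexes by up to its
#: half-width, so apexes can sit ~10 nt from the motif start.
PEAK_TOLERANCE = 10
#: SnoRNA boundaries sit this many nt outside the C and D boxes.
BOUNDARY_OFFSET = 5
#: Minimal inter-box span required to place the internal D'/C' pair.
MIN_PRIME_REGION = 12

_SMOOTH_WINDOW = 11
_SMOOTH_ORDER = 2


@dataclass(frozen=True)
class Box:
    """One motif instance: window-relative start, sequence, Hamming score."""

    start: int
    seq: str
    score: int

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class BoxAnnotation:
    """The four boxes of one candidate window (primes may be absent).

    When all four are present their starts increase strictly in the order
    C < D' < C' < D along the window.
    """

    c: Box
    d: Box
    d_prime: Optional[Box] = None
    c_prime: Optional[Box] = None

    def __post_init__(self) -> None:
        starts = [self.c.start]
        if self.d_prime is not None:
            starts.append(self.d_prime.start)
        if self.c_prime is not None:
            starts.append(self.c_prime.start)
        starts.append(self.d.start)
        if any(a >= b for a, b in zip(starts, starts[1:])):
            raise ValueError(f"box order violated: starts {starts}")


def compute_importance(classifier: WindowClassifier, window_seq: str,
                       span: int = OCCLUSION_SPAN) -> np.ndarray:
    """Occlusion importance profile, one value per nucleotide.

    value[i] = p(window) - mean over all masked variants whose N-span
    covers position i. Positive values mark nucleotides that support the
    positive call.
    """
    L = len(window_seq)
    if L < span:
        raise ValueError("window shorter than occlusion span")
    variants = [
        window_seq[:s] + "N" * span + window_seq[s + span:]
        for s in range(L - span + 1)
    ]
    try:
        probs = np.asarray(classifier.predict([window_seq] + variants), dtype=float)
    except Exception as exc:
        raise RuntimeError("window classifier failed during occlusion") from exc
    p0, masked = probs[0], probs[1:]
    profile = np.empty(L, dtype=float)
    for i in range(L):
        lo = max(0, i - span + 1)
        hi = min(L - span, i)
        profile[i] = p0 - masked[lo: hi + 1].mean()
    return profile


def detect_peaks(profile: np.ndarray) -> list[int]:
    """Local maxima of the smoothed profile exceeding the profile mean."""
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("importance profile contains non-finite values")
    window = min(_SMOOTH_WINDOW, len(profile))
    if window <= _SMOOTH_ORDER:
        smoothed = profile
    else:
        smoothed = savgol_filter(profile, window, _SMOOTH_ORDER)
    # strictly above the mean; the epsilon guards against smoothing
    # ripples on a constant profile
    height = float(profile.mean()) + 1e-9 * (abs(float(profile.mean())) + 1.0)
    peaks, _ = find_peaks(smoothed, height=height)
    return sorted(int(p) for p in peaks)


def _candidate_starts(lo: int, hi: int, peaks: Sequence[int]) -> list[int]:
    """Starts in [lo, hi] within PEAK_TOLERANCE of a peak; all if no peaks."""
    starts = range(lo, hi + 1)
    if not peaks:
        return list(starts)
    return [s for s in starts if any(abs(s - p) <= PEAK_TOLERANCE for p in peaks)]


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_STEM_ARM = 20


def stem_complementarity(window_seq: str, c_start: int, d_start: int) -> int:
    """Aligned complementary matches of the terminal arms implied by a C-D pair.

    The boundary rule puts the snoRNA ends 5 nt outside the boxes; each arm
    covers 20 nt straddling a boundary and the arms are compared in the
    fixed antiparallel register of a closed terminal stem (WC + GU pairs).
    Used to resolve ties between equal-Hamming box placements: the true
    boxes sit next to the stem, spurious motif copies usually do not.
    """
    left = window_seq[max(0, c_start - _STEM_ARM): c_start]
    right_lo = d_start + len(D_CONSENSUS)
    right = window_seq[right_lo: right_lo + _STEM_ARM]
    k = min(len(left), len(right))
    return sum(
        1 for a, b in zip(left[len(left) - k:], right[:k][::-1])
        if (a, b) in _PAIRS
    )


def find_cd_pair(window_seq: str, peaks: Sequence[int]) -> tuple[Box, Box]:
    """Best C-D box pair by minimal total Hamming distance to consensus.

    C starts are restricted to [5, L/2 - 7] (before the half-window) and D
    starts to [L/2, L - 9] (after it), keeping >= 5 nt outside each box for
    the boundary rule. When peaks exist in a half, candidates in that half
    must lie within +/-6 nt of one; otherwise every eligible start is a
    candidate. Peaks are a localization aid only: if the peak-restricted
    optimum scores worse than the unrestricted one, the restriction is
    dropped. Ties: smaller C score, then C start closest to the leftmost
    eligible peak, then leftmost C, then strongest implied terminal stem,
    then rightmost D.
    """
    L = len(window_seq)
    if L < 30:
        raise ValueError(f"window of {L} nt too short for box annotation")
    half = L // 2
    c_lo, c_hi = BOUNDARY_OFFSET, half - len(C_CONSENSUS)
    d_lo, d_hi = half, L - len(D_CONSENSUS) - BOUNDARY_OFFSET
    c_peaks = [p for p in peaks if p < half]
    d_peaks = [p for p in peaks if p >= half]
    c_starts = _candidate_starts(c_lo, c_hi, c_peaks) or list(range(c_lo, c_hi + 1))
    d_starts = _candidate_starts(d_lo, d_hi, d_peaks) or list(range(d_lo, d_hi + 1))
    leftmost_peak = min(c_peaks) if c_peaks else None

    def scored(starts: Sequence[int], consensus: str) -> list[tuple[int, int]]:
        return [
            (box_hamming(window_seq[s: s + len(consensus)], consensus), s)
            for s in starts
        ]

    def key(c: tuple[int, int], d: tuple[int, int]):
        hc, cs = c
        hd, ds = d
        peak_dist = abs(cs - leftmost_peak) if leftmost_peak is not None else 0
        return (hc + hd, hc, peak_dist, cs,
                -stem_complementarity(window_seq, cs, ds), -ds)

    def best(c_scored, d_scored):
        best_c = min(h for h, _ in c_scored)
        best_d = min(h for h, _ in d_scored)
        c_top = [c for c in c_scored if c[0] == best_c]
        d_top = [d for d in d_scored if d[0] == best_d]
        return min(((c, d) for c in c_top for d in d_top),
                   key=lambda pair: key(*pair))

    best_c, best_d = best(scored(c_starts, C_CONSENSUS),
                          scored(d_starts, D_CONSENSUS))
    if best_c[0] + best_d[0] > 0 and (c_peaks or d_peaks):
        # peak gating must never worsen the motif fit
        all_c, all_d = (scored(range(c_lo, c_hi + 1), C_CONSENSUS),
                        scored(range(d_lo, d_hi + 1), D_CONSENSUS))
        if (min(h for h, _ in all_c) + min(h for h, _ in all_d)
                < best_c[0] + best_d[0]):
            logger.debug("peak-restricted boxes scored worse than global "
                         "optimum; dropping peak restriction")
            best_c, best_d = best(all_c, all_d)
    hc, cs = best_c
    hd, ds = best_d
    return (
        Box(cs, window_seq[cs: cs + len(C_CONSENSUS)], hc),
        Box(ds, window_seq[ds: ds + len(D_CONSENSUS)], hd),
    )


def find_prime_boxes(window_seq: str, c_box: Box, d_box: Box,
                     ) -> tuple[Optional[Box], Optional[Box]]:
    """Best internal D'-C' pair (D' upstream of C') between the C and D boxes.

    Exhaustive over all ordered placements inside (C end, D start); the
    pair minimizing summed Hamming distance wins, ties broken by smaller
    D' score, then leftmost D', then leftmost C'. Returns (None, None)
    when the inter-box region is shorter than 12 nt.
    """
    lo, hi = c_box.end, d_box.start
    if hi - lo < MIN_PRIME_REGION:
        return None, None
    ld, lc = len(D_CONSENSUS), len(C_CONSENSUS)
    best = None
    best_key = None
    for dp_start in range(lo, hi - ld - lc + 1):
        dp_seq = window_seq[dp_start: dp_start + ld]
        h_dp = box_hamming(dp_seq, D_CONSENSUS)
        for cp_start in range(dp_start + ld, hi - lc + 1):
            cp_seq = window_seq[cp_start: cp_start + lc]
            h_cp = box_hamming(cp_seq, C_CONSENSUS)
            k = (h_dp + h_cp, h_dp, dp_start, cp_start)
            if best_key is None or k < best_key:
                best_key = k
                best = (Box(dp_start, dp_seq, h_dp), Box(cp_start, cp_seq, h_cp))
    if best is None:
        return None, None
    return best


def define_boundaries(c_box: Box, d_box: Box, window: GenomicInterval,
                      ) -> GenomicInterval:
    """SnoRNA locus: fifth nt upstream of C through fifth nt downstream of D.

    Window-relative boundaries are mapped to genomic coordinates; on the
    minus strand the window sequence was reverse-complemented, so relative
    positions are mirrored back through the window. Boundaries falling
    outside the window are clipped with a warning.
    """
    L = window.length
    rel_start = c_box.start - BOUNDARY_OFFSET
    rel_end = d_box.end + BOUNDARY_OFFSET
    if rel_start < 0 or rel_end > L:
        logger.warning(
            "locus boundaries [%d, %d) clipped to window of %d nt",
            rel_start, rel_end, L,
        )
        rel_start = max(rel_start, 0)
        rel_end = min(rel_end, L)
    if window.strand == "-":
        g_start = window.start + (L - rel_end)
        g_end = window.start + (L - rel_start)
    else:
        g_start = window.start + rel_start
        g_end = window.start + rel_end
    return GenomicInterval(window.chrom, g_start, g_end, window.strand)


def annotate_window(classifier: WindowClassifier, window_seq: str,
                    ) -> tuple[BoxAnnotation, np.ndarray]:
    """Full box annotation of one window: profile, peaks, C/D, D'/C'."""
    profile = compute_importance(classifier, window_seq)
    peaks = detect_peaks(profile)
    c_box, d_box = find_cd_pair(window_seq, peaks)
    d_prime, c_prime = find_prime_boxes(window_seq, c_box, d_box)
    return BoxAnnotation(c=c_box, d=d_box, d_prime=d_prime, c_prime=c_prime), profile
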