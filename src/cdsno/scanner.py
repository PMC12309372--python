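"""Sliding-window enumeration and classification over genomic sequence.

Windows of a fixed length (default 194 nt: the 164 nt snoRNA length cap
plus 15 nt of flank on each side) are enumerated on both strands at a
configurable step size and scored by a pluggable window classifier.
Minus-strand windows keep plus-strand coordinates (BED convention); their
sequence is reverse-complemented at classification time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Protocol, Sequence, Union

import numpy as np

from .core_io import FormatError, GenomicInterval, SequenceRecord, WindowPrediction

__all__ = [
    "ScanConfig",
    "WindowClassifier",
    "reverse_complement",
    "enumerate_windows",
    "extract_window_seq",
    "classify_windows",
    "scan_record",
]

logger = logging.getLogger(__name__)

#: Default window length: 164 nt length cap + 15 nt flanks on both sides.
DEFAULT_WINDOW_LENGTH = 194
#: Default step size; values up to 10 lose few candidates, larger warns.
DEFAULT_STEP_SIZE = 5
SAFE_MAX_STEP = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ScanConfig:
    window_length: int = DEFAULT_WINDOW_LENGTH
    step_size: int = DEFAULT_STEP_SIZE
    batch_size: int = 2048
    skip_n_fraction: float = 0.10
    chunk_size: int = 500_000

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if not (1 <= self.step_size <= self.window_length):
            raise ValueError("need 1 <= step_size <= window_length")
        if self.step_size > SAFE_MAX_STEP:
            logger.warning(
                "step size %d exceeds the safe range (<= %d); candidate loci "
                "may be missed", self.step_size, SAFE_MAX_STEP,
            )


class WindowClassifier(Protocol):
    """Contract for the identification-step window model.

    Maps DNA strings of the configured window length to the probability
    that the window contains a C/D box snoRNA. Must be deterministic for a
    fixed trained state.
    """

    def predict(self, seqs: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    if set(seq) - set("ACGTN"):
        raise FormatError(f"invalid characters in sequence: "
                          f"{sorted(set(seq) - set('ACGTN'))}")
    return seq.translate(_COMPLEMENT)[::-1]


def enumerate_windows(record: SequenceRecord, config: ScanConfig,
                      strand: str, region: Optional[GenomicInterval] = None,
                      ) -> list[GenomicInterval]:
    """Enumerate fixed-length windows at starts 0, s, 2s, ... <= len - L.

    Minus-strand windows carry the same plus-strand coordinates; only
    sequence extraction differs. When ``region`` is given, enumeration is
    restricted to windows fully inside it.
    """
    L, s = config.window_length, config.step_size
    lo = 0 if region is None else region.start
    hi = len(record.seq) if region is None else min(region.end, len(record.seq))
    if hi - lo < L:
        logger.warning(
            "sequence %s (%d nt available) shorter than window length %d; "
            "no windows", record.id, hi - lo, L,
        )
        return []
    return [
        GenomicInterval(record.id, start, start + L, strand)
        for start in range(lo, hi - L + 1, s)
    ]


def extract_window_seq(genome: Mapping[str, str], interval: GenomicInterval) -> str:
    """Window sequence oriented 5'->3' on the interval's strand."""
    seq = genome[interval.chrom][interval.start:interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def classify_windows(classifier: WindowClassifier,
                     windows: Sequence[GenomicInterval],
                     genome: Mapping[str, str],
                     batch_size: int = 2048,
                     skip_n_fraction: float = 0.10,
                     ) -> list[WindowPrediction]:
    """Score each window; order preserved; one probability per window.

    Windows whose sequence exceeds ``skip_n_fraction`` ambiguous bases are
    skipped (not scored). Minus-strand windows are classified on their
    reverse-complemented sequence.
    """
    kept: list[GenomicInterval] = []
    seqs: list[str] = []
    for w in windows:
        seq = extract_window_seq(genome, w)
        if seq.count("N") > skip_n_fraction * len(seq):
            logger.debug("skipping N-rich window %s:%d-%d", w.chrom, w.start, w.end)
            continue
        kept.append(w)
        seqs.append(seq)
    preds: list[WindowPrediction] = []
    for i in range(0, len(seqs), batch_size):
        batch = seqs[i : i + batch_size]
        try:
            probs = np.asarray(classifier.predict(batch), dtype=float)
        except Exception as exc:
            w = kept[i]
            raise RuntimeError(
                f"window classifier failed on batch starting at "
                f"{w.chrom}:{w.start}-{w.end}({w.strand})"
            ) from exc
        if probs.shape != (len(batch),):
            raise RuntimeError("classifier returned wrong number of probabilities")
        preds.extend(
            WindowPrediction(w, float(p))
            for w, p in zip(kept[i : i + batch_size], probs)
        )
    return preds


def scan_record(record: SequenceRecord, classifier: WindowClassifier,
                config: ScanConfig, strands: Iterable[str] = ("+", "-"),
                region: Optional[GenomicInterval] = None,
                ) -> list[WindowPrediction]:
    """Scan one sequence on the requested strands, chunked for memory.

    Long sequences are processed in chunks overlapping by L - 1 nt so no
    window is lost at chunk borders; window starts stay on the global step
    grid, so chunking never changes the result.
    """
    L, s = config.window_length, config.step_size
    genome = {record.id: record.seq}
    lo = 0 if region is None else region.start
    hi = len(record.seq) if region is None else min(region.end, len(record.seq))
    out: list[WindowPrediction] = []
    for strand in strands:
        if hi - lo < L:
            enumerate_windows(record, config, strand, region)  # emits warning
            continue
        next_start = lo  # next unemitted start on the global step grid
        chunk_lo = lo
        while chunk_lo <= hi - L:
            chunk_hi = min(chunk_lo + config.chunk_size, hi)
            windows = [
                GenomicInterval(record.id, start, start + L, strand)
                for start in range(next_start, chunk_hi - L + 1, s)
            ]
            if windows:
                next_start = windows[-1].start + s
                out.extend(
                    classify_windows(
                        classifier, windows, genome,
                        batch_size=config.batch_size,
                        skip_n_fraction=config.skip_n_fraction,
                    )
                )
            if chunk_hi == hi:
                break
            chunk_lo = chunk_hi - (L - 1)
    return out
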