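"""Domain types, coordinate conventions and flat-file readers/writers.

All coordinates are 0-based half-open (BED convention) internally; the GTF
writer is the single place where the 1-based inclusive conversion happens.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomicInterval",
    "SequenceRecord",
    "WindowPrediction",
    "AnnotatedSnoRNA",
    "CoverageTrack",
    "EXPRESSED",
    "PSEUDOGENE",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "write_predictions",
]

#: Subclass labels for the refinement step.
EXPRESSED = "expressed_CD_snoRNA"
PSEUDOGENE = "CD_snoRNA_pseudogene"

_VALID_STRANDS = {"+", "-", None}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence.

    ``strand`` may be ``None`` for strand-agnostic intervals (e.g. BED rows
    without a strand column); such regions are scanned on both strands
    downstream.
    """

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 when on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


_SEQ_ALPHABET = set("ACGTN")


def _normalize_seq(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise FormatError(f"invalid sequence characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; upper-cased, U converted to T on ingest."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalize_seq(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class WindowPrediction:
    """A scanning window together with its positive-class probability."""

    interval: GenomicInterval
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")


@dataclass
class AnnotatedSnoRNA:
    """Final prediction record emitted by the pipeline.

    ``locus`` is the boundary-defined snoRNA (not the scanning window);
    ``seq`` is the snoRNA sequence read 5'->3' on its own strand.
    ``boxes`` positions are 0-based relative to the annotated window
    sequence (also 5'->3' on the snoRNA strand).
    """

    locus: GenomicInterval
    window: GenomicInterval
    seq: str
    boxes: "object"  # cdsno.boxes.BoxAnnotation
    features: "object"  # cdsno.features.FeatureVector
    subclass: str
    prob_first: float
    prob_second: float
    id: str = ""
    window_seq: str = ""  # window sequence 5'->3' on the snoRNA strand

    def __post_init__(self) -> None:
        if not self.window.contains(self.locus):
            raise ValueError("locus must be contained in its window")


class CoverageTrack:
    """Strand-specific per-base read depth.

    Positions absent from the track have depth 0. Depth arrays grow lazily
    per (chromosome, strand) as intervals are added.
    """

    def __init__(self) -> None:
        self._depth: dict[tuple[str, str], np.ndarray] = {}

    def add(self, chrom: str, start: int, end: int, value: float, strand: str) -> None:
        if value < 0:
            raise FormatError(f"negative coverage value {value}")
        if not (0 <= start < end):
            raise FormatError(f"invalid bedGraph interval {start}-{end}")
        key = (chrom, strand)
        arr = self._depth.get(key)
        if arr is None or len(arr) < end:
            new = np.zeros(max(end, 0 if arr is None else 2 * len(arr)), dtype=float)
            if arr is not None:
                new[: len(arr)] = arr
            self._depth[key] = new
            arr = new
        arr[start:end] += value

    def depth(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); absent positions are 0."""
        if end <= start:
            raise ValueError("empty query interval")
        out = np.zeros(end - start, dtype=float)
        arr = self._depth.get((chrom, strand))
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def chroms(self) -> list[tuple[str, str]]:
        return sorted(self._depth)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: not FASTA-formatted (missing '>' header)")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Read a BED file (>=3 columns) into 0-based half-open intervals.

    Rows without a strand column (or with strand '.') yield intervals with
    ``strand=None``, which the scanner treats as "scan both strands".
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand: Optional[str] = None
            if len(cols) >= 6 and cols[5] in ("+", "-"):
                strand = cols[5]
            try:
                intervals.append(GenomicInterval(cols[0], start, end, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path],
              names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand or '.'}\n"
            )


def read_bedgraph(path: Union[str, Path], strand: str,
                  track: Optional[CoverageTrack] = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Overlapping records accumulate (their values sum at overlapping bases).
    Pass an existing ``track`` to load multiple files (e.g. both strands)
    into one object.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if track is None:
        track = CoverageTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph row") from exc
            try:
                track.add(cols[0], start, end, value, strand)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_bedgraph(track: CoverageTrack, strand: str, path: Union[str, Path]) -> None:
    """Write one strand of a coverage track as a run-length bedGraph."""
    with open(path, "w") as fh:
        for chrom, s in track.chroms():
            if s != strand:
                continue
            arr = track._depth[(chrom, s)]
            run_start = None
            run_val = 0.0
            for pos in range(len(arr) + 1):
                val = arr[pos] if pos < len(arr) else 0.0
                if run_start is not None and val != run_val:
                    if run_val != 0:
                        fh.write(f"{chrom}\t{run_start}\t{pos}\t{run_val:g}\n")
                    run_start = pos if val != 0 else None
                    run_val = val
                elif run_start is None and val != 0:
                    run_start = pos
                    run_val = val


# ---------------------------------------------------------------------------
# prediction writer
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "prediction_id", "chrom", "start", "end", "strand", "subclass",
    "prob_first", "prob_second", "sequence",
    "c_start", "c_seq", "d_prime_start", "d_prime_seq",
    "c_prime_start", "c_prime_seq", "d_start", "d_seq",
    "c_score", "d_score", "cumulative_score",
    "terminal_stem_score", "structural_score",
]


def _box_fields(box) -> tuple[str, str]:
    if box is None:
        return "", ""
    return str(box.start), box.seq


def write_predictions(records: Sequence[AnnotatedSnoRNA], path: Union[str, Path],
                      fmt: str = "tsv") -> None:
    """Write final predictions as TSV, BED, GTF or FASTA.

    BED output is 0-based half-open with the subclass in the name field;
    GTF output is 1-based inclusive. Box positions in the TSV are 0-based
    relative to the annotated window sequence, read 5'->3' on the snoRNA
    strand.
    """
    if fmt not in ("tsv", "bed", "gtf", "fasta"):
        raise ValueError(f"unknown output format {fmt!r}")
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for rec in records:
                b = rec.boxes
                f = rec.features
                row = [
                    rec.id, rec.locus.chrom, str(rec.locus.start),
                    str(rec.locus.end), rec.locus.strand or ".", rec.subclass,
                    f"{rec.prob_first:.6f}", f"{rec.prob_second:.6f}", rec.seq,
                    *_box_fields(b.c), *_box_fields(b.d_prime),
                    *_box_fields(b.c_prime), *_box_fields(b.d),
                    str(f.c_score), str(f.d_score), str(f.cumulative_score),
                    f"{f.terminal_stem_score:.3f}", f"{f.structural_score:.4f}",
                ]
                fh.write("\t".join(row) + "\n")
        elif fmt == "bed":
            for rec in records:
                name = f"{rec.id}|{rec.subclass}"
                fh.write(
                    f"{rec.locus.chrom}\t{rec.locus.start}\t{rec.locus.end}\t"
                    f"{name}\t{rec.prob_first:.4f}\t{rec.locus.strand or '.'}\n"
                )
        elif fmt == "gtf":
            for rec in records:
                attrs = (
                    f'gene_id "{rec.id}"; subclass "{rec.subclass}"; '
                    f'prob_first "{rec.prob_first:.4f}"; '
                    f'prob_second "{rec.prob_second:.4f}";'
                )
                fh.write(
                    f"{rec.locus.chrom}\tcdsno\tgene\t{rec.locus.start + 1}\t"
                    f"{rec.locus.end}\t.\t{rec.locus.strand or '.'}\t.\t{attrs}\n"
                )
        else:  # fasta
            for rec in records:
                header = (
                    f"{rec.id}|{rec.locus.chrom}:{rec.locus.start}-"
                    f"{rec.locus.end}({rec.locus.strand or '.'})|{rec.subclass}"
                )
                fh.write(f">{header}\n{rec.seq}\n")
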