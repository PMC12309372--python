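"""Expression-determinant feature scores for candidate C/D box snoRNAs.

Five scores are computed per candidate: the C and D box Hamming scores
(mutations vs the RTGATGA / CTGA consensus), the cumulative box score
(sum over C, D, C' and D'), the terminal-stem score (stem length x duplex
stability of the two terminal arms, kcal*nt/mol) and the structural score
(secondary-structure minimum free energy normalized by snoRNA length,
kcal/mol per nt). Folding goes through a small engine contract: ViennaRNA
when its Python bindings are importable, otherwise a built-in Nussinov
maximum-pairing engine (-1 kcal/mol per canonical pair, minimum hairpin
loop 3). DNA strings are folded as RNA (T read as U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, Optional, Protocol

__all__ = [
    "C_CONSENSUS",
    "D_CONSENSUS",
    "FeatureVector",
    "FoldingEngine",
    "NussinovEngine",
    "ViennaEngine",
    "default_engine",
    "box_hamming",
    "structural_score",
    "terminal_stem_score",
    "feature_vector",
]

if TYPE_CHECKING:  # pragma: no cover
    from .boxes import BoxAnnotation

logger = logging.getLogger(__name__)

#: C/C' box consensus (R = A or G at zero cost).
C_CONSENSUS = "RTGATGA"
#: D/D' box consensus.
D_CONSENSUS = "CTGA"

#: Maximal Hamming penalty charged for an absent C' / D' box.
MAX_C_PRIME_SCORE = len(C_CONSENSUS)
MAX_D_PRIME_SCORE = len(D_CONSENSUS)

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "N": {"A", "C", "G", "T"},
}

_CANONICAL_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


def box_hamming(observed: str, consensus: str) -> int:
    """Mutation count of an observed box against a degenerate consensus."""
    if len(observed) != len(consensus):
        raise ValueError(
            f"length mismatch: {len(observed)} vs consensus {len(consensus)}"
        )
    return sum(
        1 for o, c in zip(observed, consensus)
        if o not in _IUPAC.get(c, {c})
    )


@dataclass(frozen=True)
class FeatureVector:
    c_score: int
    d_score: int
    c_prime_score: int
    d_prime_score: int
    cumulative_score: int
    terminal_stem_score: float  # kcal*nt/mol, <= 0
    structural_score: float  # kcal/mol per nt, <= 0

    def __post_init__(self) -> None:
        expected = (self.c_score + self.d_score
                    + self.c_prime_score + self.d_prime_score)
        if self.cumulative_score != expected:
            raise ValueError("cumulative_score must equal the sum of box scores")
        if self.terminal_stem_score > 0 or self.structural_score > 0:
            raise ValueError("stability scores must be <= 0")


class FoldingEngine(Protocol):
    """Folding contract: single-sequence MFE and two-sequence duplex fold."""

    def mfe(self, seq: str) -> float:  # pragma: no cover
        ...

    def cofold(self, seq_a: str, seq_b: str) -> tuple[float, int]:
        """Return (duplex MFE in kcal/mol, number of intermolecular pairs)."""
        ...  # pragma: no cover


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL_PAIRS


class NussinovEngine:
    """Maximum canonical base pairing with a fixed -1 kcal/mol per pair.

    Pairs are AU, GC and GU wobble (on the DNA alphabet: AT, GC, GT);
    hairpin loops must span at least ``min_loop`` unpaired nucleotides.
    ``cofold`` scores the pure intermolecular duplex: non-crossing pairs
    between the two strands only, both read 5'->3' (position i of the
    first strand pairs with position j of the second such that pairs
    nest like the two arms of a stem).
    """

    min_loop = 3
    pair_energy = -1.0

    def mfe(self, seq: str) -> float:
        n = len(seq)
        if n == 0:
            return 0.0
        # dp[i][j] = max pairs in seq[i..j]
        dp = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i][j - 1]
                for k in range(i, j - self.min_loop):
                    if _pairs(seq[k], seq[j]):
                        left = dp[i][k - 1] if k > i else 0
                        inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        best = max(best, left + inner + 1)
                dp[i][j] = best
        return dp[0][n - 1] * self.pair_energy

    def cofold(self, seq_a: str, seq_b: str) -> tuple[float, int]:
        la, lb = len(seq_a), len(seq_b)
        # dp[i][j] = max duplex pairs between seq_a[i:] and seq_b[:j],
        # pairing a ascending against b descending (stem geometry).
        dp = [[0] * (lb + 1) for _ in range(la + 1)]
        for i in range(la - 1, -1, -1):
            for j in range(1, lb + 1):
                best = max(dp[i + 1][j], dp[i][j - 1])
                if _pairs(seq_a[i], seq_b[j - 1]):
                    best = max(best, dp[i + 1][j - 1] + 1)
                dp[i][j] = best
        n_pairs = dp[0][lb]
        return n_pairs * self.pair_energy, n_pairs


class ViennaEngine:
    """Thermodynamic folding through the ViennaRNA Python bindings."""

    def __init__(self) -> None:
        import RNA  # noqa: F401 — fails here if bindings are absent

        self._rna = RNA

    def mfe(self, seq: str) -> float:
        structure, energy = self._rna.fold(seq.replace("T", "U"))
        if "(" not in structure:
            return 0.0
        return min(0.0, float(energy))

    def cofold(self, seq_a: str, seq_b: str) -> tuple[float, int]:
        rna = seq_a.replace("T", "U") + "&" + seq_b.replace("T", "U")
        structure, energy = self._rna.cofold(rna)
        cut = len(seq_a)
        stack: list[int] = []
        inter = 0
        for pos, ch in enumerate(structure):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                opener = stack.pop()
                if opener < cut <= pos:
                    inter += 1
        if inter == 0:
            return 0.0, 0
        return min(0.0, float(energy)), inter


@lru_cache(maxsize=1)
def default_engine() -> FoldingEngine:
    """ViennaRNA when importable, otherwise the built-in Nussinov engine."""
    try:
        engine: FoldingEngine = ViennaEngine()
        logger.info("using ViennaRNA folding engine")
    except ImportError:
        engine = NussinovEngine()
        logger.info("ViennaRNA bindings not found; using Nussinov engine")
    return engine


def structural_score(sno_seq: str, engine: Optional[FoldingEngine] = None) -> float:
    """Secondary-structure MFE of the snoRNA divided by its length."""
    if not sno_seq:
        raise ValueError("empty snoRNA sequence")
    engine = engine or default_engine()
    try:
        mfe = engine.mfe(sno_seq)
    except Exception as exc:
        raise RuntimeError(
            f"folding engine {type(engine).__name__} failed on mfe()"
        ) from exc
    return mfe / len(sno_seq)


def terminal_stem_score(window_seq: str, locus_rel_start: int,
                        locus_rel_end: int,
                        engine: Optional[FoldingEngine] = None,
                        arm_length: int = 20) -> float:
    """Stem length x duplex stability of the two terminal arms.

    Each arm covers ``arm_length`` nt straddling a snoRNA boundary: by
    default 15 nt of flank plus the outermost 5 nt of the snoRNA (the
    left arm ends 5 nt inside the 5' end; the right arm starts 5 nt
    inside the 3' end). Arms are clipped at window edges with a warning.
    The score is (number of intermolecular base pairs) x (duplex MFE).
    """
    if arm_length < 5:
        raise ValueError("arm_length must be >= 5")
    if not (0 <= locus_rel_start < locus_rel_end <= len(window_seq)):
        raise ValueError("locus must lie within the window")
    engine = engine or default_engine()
    left_lo = locus_rel_start + 5 - arm_length
    right_hi = locus_rel_end - 5 + arm_length
    if left_lo < 0 or right_hi > len(window_seq):
        logger.warning(
            "terminal-stem arms clipped at window edges "
            "(left_lo=%d, right_hi=%d, window=%d nt)",
            left_lo, right_hi, len(window_seq),
        )
    left = window_seq[max(0, left_lo): locus_rel_start + 5]
    right = window_seq[locus_rel_end - 5: min(len(window_seq), right_hi)]
    try:
        duplex_mfe, n_pairs = engine.cofold(left, right)
    except Exception as exc:
        raise RuntimeError(
            f"folding engine {type(engine).__name__} failed on cofold()"
        ) from exc
    return n_pairs * duplex_mfe


def feature_vector(window_seq: str, boxes: "BoxAnnotation",
                   locus_rel_start: int, locus_rel_end: int,
                   engine: Optional[FoldingEngine] = None,
                   arm_length: int = 20) -> FeatureVector:
    """Assemble the five expression-determinant scores for one candidate.

    Absent C'/D' boxes are charged their maximal Hamming penalty (7 and 4)
    so the cumulative score stays comparable across candidates.
    """
    engine = engine or default_engine()
    c_score = boxes.c.score
    d_score = boxes.d.score
    c_prime = boxes.c_prime.score if boxes.c_prime is not None else MAX_C_PRIME_SCORE
    d_prime = boxes.d_prime.score if boxes.d_prime is not None else MAX_D_PRIME_SCORE
    sno_seq = window_seq[locus_rel_start:locus_rel_end]
    return FeatureVector(
        c_score=c_score,
        d_score=d_score,
        c_prime_score=c_prime,
        d_prime_score=d_prime,
        cumulative_score=c_score + d_score + c_prime + d_prime,
        terminal_stem_score=terminal_stem_score(
            window_seq, locus_rel_start, locus_rel_end, engine, arm_length
        ),
        structural_score=structural_score(sno_seq, engine),
    )
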