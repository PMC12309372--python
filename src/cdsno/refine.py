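"""Second-stage refinement: expressed C/D snoRNA versus snoRNA pseudogene.

A pluggable subclass classifier assigns each candidate a probability of
being expressed; candidates are split into high- and low-confidence calls
by the p2 threshold on the probability of the predicted class, then a
rule cascade over the expression-determinant features adjusts the label.
By design the cascade favors the expressed class: a high-confidence
expressed call is never overturned, while a high-confidence pseudogene
call is overturned when at least 4 of the 5 features are favorable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .core_io import EXPRESSED, PSEUDOGENE, AnnotatedSnoRNA
from .features import FeatureVector

__all__ = [
    "RefineConfig",
    "SubclassClassifier",
    "count_favorable",
    "apply_rule_cascade",
    "refine_candidates",
    "N_FEATURES",
]

logger = logging.getLogger(__name__)

#: Number of expression-determinant features entering the favorable count.
N_FEATURES = 5


@dataclass(frozen=True)
class RefineConfig:
    """Confidence threshold and per-feature favorable cutoffs.

    The terminal-stem cutoff (-25 kcal*nt/mol) and the C/D box rules are
    printed pipeline constants; the cumulative (<= 2) and structural
    (<= -0.2 kcal/mol/nt) cutoffs correspond to distribution-derived
    thresholds and are configurable.
    """

    p2: float = 0.999
    max_c_score: int = 1
    max_d_score: int = 0
    max_cumulative_score: int = 2
    max_terminal_stem_score: float = -25.0
    max_structural_score: float = -0.2
    min_favorable_low_conf: int = 2
    min_favorable_overturn: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.p2 <= 1.0):
            raise ValueError("p2 must be in (0, 1]")


class SubclassClassifier(Protocol):
    """Contract for the refinement-step model.

    Maps window sequences to the probability that the contained snoRNA is
    expressed (vs a pseudogene). Deterministic for a fixed trained state.
    """

    def predict(self, seqs: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


def count_favorable(features: FeatureVector,
                    config: RefineConfig = RefineConfig()) -> int:
    """How many of the five features meet their favorable-for-expression cutoff."""
    return sum([
        features.c_score <= config.max_c_score,
        features.d_score <= config.max_d_score,
        features.cumulative_score <= config.max_cumulative_score,
        features.terminal_stem_score <= config.max_terminal_stem_score,
        features.structural_score <= config.max_structural_score,
    ])


def apply_rule_cascade(subclass_label: str, prob_second: float,
                       features: FeatureVector,
                       config: RefineConfig = RefineConfig()) -> str:
    """Confidence-dependent rule cascade over the classifier's label.

    High confidence (prob_second >= p2): the label is kept, except that a
    pseudogene call is overturned to expressed when >= 4 features are
    favorable. Low confidence: the first firing rule decides —
    (i) pseudogene if C score >= 2 and D score >= 1;
    (ii) expressed if terminal-stem score <= -25 kcal*nt/mol;
    (iii) pseudogene if < 2 features are favorable;
    otherwise the classifier's label passes through.
    """
    if subclass_label not in (EXPRESSED, PSEUDOGENE):
        raise ValueError(f"unknown subclass label {subclass_label!r}")
    if not (0.0 <= prob_second <= 1.0):
        raise ValueError("prob_second outside [0, 1]")
    n_fav = count_favorable(features, config)
    if prob_second >= config.p2:
        if subclass_label == PSEUDOGENE and n_fav >= config.min_favorable_overturn:
            return EXPRESSED
        return subclass_label
    if features.c_score >= 2 and features.d_score >= 1:
        return PSEUDOGENE
    if features.terminal_stem_score <= config.max_terminal_stem_score:
        return EXPRESSED
    if n_fav < config.min_favorable_low_conf:
        return PSEUDOGENE
    return subclass_label


def refine_candidates(candidates: Sequence[AnnotatedSnoRNA],
                      classifier: SubclassClassifier,
                      config: RefineConfig = RefineConfig(),
                      ) -> list[AnnotatedSnoRNA]:
    """Assign prob_second and a final subclass to every candidate.

    The classifier is run on the window sequence; its raw label is
    expressed when p(expressed) >= 0.5 and the reported prob_second is the
    probability of the predicted class (the model's confidence), which the
    cascade compares against p2.
    """
    if not candidates:
        return []
    try:
        probs = np.asarray(
            classifier.predict([c.window_seq for c in candidates]), dtype=float
        )
    except Exception as exc:
        raise RuntimeError("subclass classifier failed") from exc
    outcomes: Counter[str] = Counter()
    refined = []
    for cand, p_expressed in zip(candidates, probs):
        raw = EXPRESSED if p_expressed >= 0.5 else PSEUDOGENE
        confidence = p_expressed if raw == EXPRESSED else 1.0 - p_expressed
        final = apply_rule_cascade(raw, confidence, cand.features, config)
        outcomes[f"{raw}->{final}"] += 1
        cand.subclass = final
        cand.prob_second = float(confidence)
        refined.append(cand)
    logger.info("refinement outcomes: %s", dict(outcomes))
    return refined
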