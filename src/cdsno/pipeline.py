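"""End-to-end orchestration: scan -> merge -> annotate -> score -> refine."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .boxes import BOUNDARY_OFFSET, annotate_window, define_boundaries
from .core_io import EXPRESSED, AnnotatedSnoRNA, GenomicInterval, SequenceRecord
from .features import FoldingEngine, feature_vector
from .merger import MergeConfig, merge_predictions
from .refine import RefineConfig, SubclassClassifier, refine_candidates
from .scanner import ScanConfig, WindowClassifier, extract_window_seq, scan_record

__all__ = ["PipelineConfig", "predict_record", "predict_records"]

logger = logging.getLogger(__name__)

#: Subclass placeholder when the refinement model is skipped.
UNREFINED = "CD_snoRNA"

#: Length cap above which an annotated locus is flagged as suspect.
MAX_LOCUS_LENGTH = 164


@dataclass(frozen=True)
class PipelineConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    first_model_only: bool = False
    rescue_best_window: bool = False
    arm_length: int = 20


def predict_record(record: SequenceRecord,
                   window_classifier: WindowClassifier,
                   subclass_classifier: Optional[SubclassClassifier] = None,
                   config: PipelineConfig = PipelineConfig(),
                   engine: Optional[FoldingEngine] = None,
                   strands: Iterable[str] = ("+", "-"),
                   region: Optional[GenomicInterval] = None,
                   ) -> list[AnnotatedSnoRNA]:
    """Run the full pipeline on one sequence.

    Returns one annotated record per retained candidate block. With
    ``config.first_model_only`` (or no subclass classifier) the
    refinement step is skipped and records carry the generic subclass.
    """
    genome = {record.id: record.seq}
    predictions = scan_record(record, window_classifier, config.scan,
                              strands=strands, region=region)
    centers = merge_predictions(
        predictions, window_classifier, genome, config.scan.step_size,
        config.merge, rescue_best_window=config.rescue_best_window,
    )
    logger.info("%s: %d windows scanned, %d candidate loci",
                record.id, len(predictions), len(centers))
    candidates: list[AnnotatedSnoRNA] = []
    for center in centers:
        window_seq = extract_window_seq(genome, center.interval)
        annotation, _profile = annotate_window(window_classifier, window_seq)
        locus = define_boundaries(annotation.c, annotation.d, center.interval)
        rel_start = max(0, annotation.c.start - BOUNDARY_OFFSET)
        rel_end = min(len(window_seq), annotation.d.end + BOUNDARY_OFFSET)
        feats = feature_vector(window_seq, annotation, rel_start, rel_end,
                               engine=engine, arm_length=config.arm_length)
        if locus.length > MAX_LOCUS_LENGTH:
            logger.warning(
                "annotated locus %s:%d-%d is %d nt, above the %d nt cap",
                locus.chrom, locus.start, locus.end, locus.length,
                MAX_LOCUS_LENGTH,
            )
        candidates.append(AnnotatedSnoRNA(
            locus=locus,
            window=center.interval,
            seq=window_seq[rel_start:rel_end],
            boxes=annotation,
            features=feats,
            subclass=UNREFINED,
            prob_first=center.probability,
            prob_second=0.5,
            window_seq=window_seq,
        ))
    if not config.first_model_only and subclass_classifier is not None:
        candidates = refine_candidates(candidates, subclass_classifier,
                                       config.refine)
    return candidates


def predict_records(records: Sequence[SequenceRecord],
                    window_classifier: WindowClassifier,
                    subclass_classifier: Optional[SubclassClassifier] = None,
                    config: PipelineConfig = PipelineConfig(),
                    engine: Optional[FoldingEngine] = None,
                    regions: Optional[Sequence[GenomicInterval]] = None,
                    ) -> list[AnnotatedSnoRNA]:
    """Run the pipeline over several sequences (optionally BED regions).

    Regions with an unspecified strand are scanned on both strands.
    Prediction ids are assigned in output order (CD_1, CD_2, ...).
    """
    by_id = {r.id: r for r in records}
    out: list[AnnotatedSnoRNA] = []
    if regions is None:
        for record in records:
            out.extend(predict_record(
                record, window_classifier, subclass_classifier, config, engine
            ))
    else:
        for region in regions:
            if region.chrom not in by_id:
                raise KeyError(f"region chromosome {region.chrom!r} not in FASTA")
            strands = (region.strand,) if region.strand else ("+", "-")
            out.extend(predict_record(
                by_id[region.chrom], window_classifier, subclass_classifier,
                config, engine, strands=strands, region=region,
            ))
    for i, rec in enumerate(out, 1):
        rec.id = f"CD_{i}"
    return out
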