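"""Per-annotation-set region classification of variants.

Each variant receives exactly one top-level category per annotation set.
Per-transcript categories are computed first (CDS / UTR / ncRNA-exonic /
splice-window intronic / intronic / promoter) and the most severe one wins:

    CDS > SPLICE > UTR5 > UTR3 > NCRNA_EXONIC > INTRONIC > PROMOTER > INTERGENIC

SPLICE is an intronic property: an intronic position within the splice
window (default 2 bp) of an exon/intron boundary of a multi-exon
transcript. Exonic bases near a boundary keep their exonic category.
PROMOTER is the window (default 1 kb) upstream of a transcription start
site on the transcript's strand; an intragenic call in any transcript
always beats a promoter call (upstream never outranks inside-a-gene).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import (
    AnnotationSet,
    EXONIC_OR_SPLICE,
    RegionCall,
    RegionCategory,
    Thresholds,
    TranscriptCall,
    TranscriptModel,
    Variant,
)

logger = logging.getLogger(__name__)


def promoter_interval(
    tx: TranscriptModel,
    window: int,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> Optional[tuple[int, int]]:
    """1-based inclusive promoter interval upstream of the TSS, strand-aware.

    Plus strand: [TSS - window, TSS - 1]; minus strand: [TSS + 1,
    TSS + window]. Clamped to [1, contig length] when lengths are known;
    returns ``None`` if the window is entirely off-contig.
    """
    if tx.strand == "+":
        lo, hi = tx.tss - window, tx.tss - 1
    else:
        lo, hi = tx.tss + 1, tx.tss + window
    lo = max(lo, 1)
    if contig_lengths is not None and tx.contig in contig_lengths:
        hi = min(hi, contig_lengths[tx.contig])
    if lo > hi:
        return None
    return lo, hi


def transcript_category(
    tx: TranscriptModel, position: int, thresholds: Thresholds
) -> Optional[RegionCategory]:
    """Category contributed by one transcript, or None if unrelated.

    Promoter hits are not reported here (they depend on footprint exclusion
    across transcripts); see :func:`classify_variant`.
    """
    if position < tx.start or position > tx.end:
        return None
    exon_hit = None
    for exon in tx.exons:
        if position in exon:
            exon_hit = exon
            break
    if exon_hit is not None:
        if tx.cds_span is None:
            return RegionCategory.NCRNA_EXONIC
        cs, ce = tx.cds_span
        if cs <= position <= ce:
            return RegionCategory.CDS
        if position < cs:
            return RegionCategory.UTR5 if tx.strand == "+" else RegionCategory.UTR3
        return RegionCategory.UTR3 if tx.strand == "+" else RegionCategory.UTR5
    # intronic: distance to the nearest exon boundary (1 = first intron base)
    dist = None
    for left, right in zip(tx.exons, tx.exons[1:]):
        if left.end < position < right.start:
            dist = min(position - left.end, right.start - position)
            break
    assert dist is not None, "position inside footprint but in no exon or intron"
    if dist <= thresholds.splice_window_bp and len(tx.exons) > 1:
        return RegionCategory.SPLICE
    return RegionCategory.INTRONIC


class AnnotationIndex:
    """Interval index over transcript footprints plus promoter windows."""

    def __init__(
        self,
        annotation_set: AnnotationSet,
        thresholds: Thresholds = Thresholds(),
        contig_lengths: Optional[Mapping[str, int]] = None,
    ):
        self.annotation_set = annotation_set
        self.thresholds = thresholds
        self.contig_lengths = dict(contig_lengths) if contig_lengths else None
        self._trees: dict[str, IntervalTree] = {}
        for tx in annotation_set.transcripts:
            tree = self._trees.setdefault(tx.contig, IntervalTree())
            lo, hi = tx.start, tx.end
            prom = promoter_interval(tx, thresholds.promoter_window_bp, self.contig_lengths)
            if prom is not None:
                lo, hi = min(lo, prom[0]), max(hi, prom[1])
            tree.addi(lo, hi + 1, tx)

    @property
    def contigs(self) -> set[str]:
        return set(self._trees)

    def query(self, contig: str, position: int) -> list[TranscriptModel]:
        """Transcripts whose footprint or promoter window contains position."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[position]]
        return sorted(hits, key=lambda tx: tx.transcript_id)


def build_index(
    annotation_set: AnnotationSet,
    thresholds: Thresholds = Thresholds(),
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> AnnotationIndex:
    return AnnotationIndex(annotation_set, thresholds, contig_lengths)


def classify_variant(
    variant: Variant,
    annotation_set: AnnotationSet,
    thresholds: Thresholds = Thresholds(),
    index: Optional[AnnotationIndex] = None,
    use_promoter: bool = True,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> RegionCall:
    """Assign the variant its top-level category under one annotation set.

    ``use_promoter=False`` disables the PROMOTER category (upstream
    positions then fall back to INTERGENIC), mirroring baseline-style
    annotation runs that only distinguish genic from intergenic.
    """
    if index is None:
        index = build_index(annotation_set, thresholds, contig_lengths)
    if variant.contig not in index.contigs:
        logger.warning(
            "variant %s: contig %r absent from annotation set %r; INTERGENIC",
            variant.id,
            variant.contig,
            annotation_set.name,
        )
    calls: list[TranscriptCall] = []
    promoter_genes: set[str] = set()
    for tx in index.query(variant.contig, variant.position):
        cat = transcript_category(tx, variant.position, thresholds)
        if cat is None:
            prom = promoter_interval(tx, thresholds.promoter_window_bp, index.contig_lengths)
            if use_promoter and prom is not None and prom[0] <= variant.position <= prom[1]:
                calls.append(
                    TranscriptCall(tx.transcript_id, tx.gene_id, RegionCategory.PROMOTER)
                )
                promoter_genes.add(tx.gene_id)
            continue
        calls.append(TranscriptCall(tx.transcript_id, tx.gene_id, cat))
    if not calls:
        return RegionCall(
            variant_id=variant.id,
            set_name=annotation_set.name,
            category=RegionCategory.INTERGENIC,
        )
    top = min(tc.category.precedence for tc in calls)
    top_cat = list(RegionCategory)[top]
    genes = sorted({tc.gene_id for tc in calls if tc.category is top_cat})
    return RegionCall(
        variant_id=variant.id,
        set_name=annotation_set.name,
        category=top_cat,
        gene_ids=tuple(genes),
        transcript_calls=tuple(sorted(calls, key=lambda tc: tc.transcript_id)),
    )


def classify_all(
    variants: Sequence[Variant],
    annotation_set: AnnotationSet,
    thresholds: Thresholds = Thresholds(),
    use_promoter: bool = True,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> dict[str, RegionCall]:
    """Classify every variant against one set, keyed by variant id."""
    index = build_index(annotation_set, thresholds, contig_lengths)
    return {
        v.id: classify_variant(
            v, annotation_set, thresholds, index=index, use_promoter=use_promoter
        )
        for v in variants
    }


def filter_noncoding(
    variants: Sequence[Variant],
    baseline: AnnotationSet,
    thresholds: Thresholds = Thresholds(),
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[list[Variant], list[Variant]]:
    """Split variants into (noncoding-by-baseline, removed).

    A variant is removed when the baseline set places it in an exonic
    region of a protein-coding gene (CDS or UTR) or in a splice-boundary
    window; ncRNA-exonic, intronic, promoter-window and intergenic
    variants are retained. The partition is exact.
    """
    if baseline.role != "baseline":
        raise ValueError(f"annotation set {baseline.name!r} does not have the baseline role")
    index = build_index(baseline, thresholds, contig_lengths)
    kept: list[Variant] = []
    removed: list[Variant] = []
    for v in variants:
        call = classify_variant(v, baseline, thresholds, index=index)
        (removed if call.category in EXONIC_OR_SPLICE else kept).append(v)
    return kept, removed


def category_counts(calls: Iterable[RegionCall]) -> pd.DataFrame:
    """Count variants per (annotation set, category).

    Returns a DataFrame indexed by set name with one column per category
    (all categories present, zero-filled); each row sums to that set's
    number of classified variants.
    """
    cols = [cat.value for cat in RegionCategory]
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        row = counts.setdefault(call.set_name, {c: 0 for c in cols})
        row[call.category.value] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", dtype=int)
    if df.empty:
        return pd.DataFrame(columns=cols, dtype=int)
    return df.reindex(columns=cols, fill_value=0).sort_index()
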