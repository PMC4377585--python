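"""Domain types shared by every stage of the re-annotation engine.

All genomic coordinates held in these types are 1-based and inclusive on
both ends; conversion from 0-based half-open conventions (BED, genePred)
happens in :mod:`reannot.io` and nowhere else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

VALID_BASES = frozenset("ACGT")

STOP_AA = "*"


class ReannotError(ValueError):
    """Raised when a domain-type invariant is violated."""


class RegionCategory(enum.Enum):
    """Top-level functional category of a variant under one annotation set.

    Exactly one category is assigned per (variant, annotation set). When a
    position is covered by several transcripts the highest-precedence
    category wins; precedence follows the severity ordering used by
    gene-based annotators (coding first, upstream last).
    """

    CDS = "CDS"
    SPLICE = "SPLICE"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NCRNA_EXONIC = "NCRNA_EXONIC"
    INTRONIC = "INTRONIC"
    PROMOTER = "PROMOTER"
    INTERGENIC = "INTERGENIC"

    @property
    def precedence(self) -> int:
        """Smaller value = higher precedence (more severe)."""
        return _CATEGORY_ORDER[self]


_CATEGORY_ORDER: Mapping[RegionCategory, int] = {
    cat: i for i, cat in enumerate(RegionCategory)
}

#: Categories removed by the baseline "noncoding" filter: exonic regions of
#: protein-coding genes plus splice-boundary windows.
EXONIC_OR_SPLICE = frozenset(
    {RegionCategory.CDS, RegionCategory.SPLICE, RegionCategory.UTR5, RegionCategory.UTR3}
)


class ConsequenceKind(enum.Enum):
    UNKNOWN = "UNKNOWN"
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    STOPGAIN = "STOPGAIN"
    STOPLOSS = "STOPLOSS"


#: Severity used when summarising over transcripts: stop-gain and stop-loss
#: rank equally above non-synonymous, which outranks synonymous; UNKNOWN is
#: least informative.
CONSEQUENCE_SEVERITY: Mapping[ConsequenceKind, int] = {
    ConsequenceKind.STOPGAIN: 3,
    ConsequenceKind.STOPLOSS: 3,
    ConsequenceKind.NONSYNONYMOUS: 2,
    ConsequenceKind.SYNONYMOUS: 1,
    ConsequenceKind.UNKNOWN: 0,
}


class RegulatoryFeatureClass(enum.Enum):
    """Regulatory evidence classes consumed as local interval tracks."""

    PROMOTER_ENHANCER = "PROMOTER_ENHANCER"
    MOTIF = "MOTIF"
    DNASE_FOOTPRINT = "DNASE_FOOTPRINT"
    EQTL = "EQTL"
    CONSERVED = "CONSERVED"
    TFBS = "TFBS"
    PROTEIN_BINDING = "PROTEIN_BINDING"


@dataclass(frozen=True)
class Thresholds:
    """Tunable windows and cut-offs of the method.

    splice_window_bp
        Intronic positions within this many bases of an exon/intron
        boundary are classified SPLICE (default 2 bp).
    promoter_window_bp
        Extent of the promoter upstream of a transcription start site,
        on the transcript strand (default 1000 bp = 1 kb).
    expression_sd_max
        A gene is called expressed in a tissue when the posterior standard
        deviation of its expression estimate is strictly below this value
        (default 1.5).
    """

    splice_window_bp: int = 2
    promoter_window_bp: int = 1000
    expression_sd_max: float = 1.5

    def __post_init__(self) -> None:
        if self.splice_window_bp <= 0:
            raise ReannotError("splice_window_bp must be strictly positive")
        if self.promoter_window_bp <= 0:
            raise ReannotError("promoter_window_bp must be strictly positive")
        if self.expression_sd_max <= 0:
            raise ReannotError("expression_sd_max must be strictly positive")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant with 1-based position.

    Alleles may be absent (``None``) — trait-association catalogs often
    omit allele detail — in which case coding consequences are UNKNOWN.
    """

    id: str
    contig: str
    position: int
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    trait: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ReannotError(
                f"variant {self.id!r}: position must be >= 1 (1-based), got {self.position}"
            )
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele is not None:
                if len(allele) != 1 or allele not in VALID_BASES:
                    raise ReannotError(
                        f"variant {self.id!r}: {name} allele {allele!r} is not a single base in ACGT"
                    )
        if (
            self.ref_allele is not None
            and self.alt_allele is not None
            and self.ref_allele == self.alt_allele
        ):
            raise ReannotError(f"variant {self.id!r}: ref and alt alleles are identical")


def validate_variant(v: Variant) -> Variant:
    """Return ``v`` unchanged if it is a well-formed SNV, else raise.

    Construction already enforces position and allele invariants; this
    additionally rejects malformed identifiers (empty / whitespace).
    """
    if not isinstance(v, Variant):
        raise ReannotError(f"not a Variant: {v!r}")
    if not v.id or v.id.strip() != v.id or not v.id.strip():
        raise ReannotError(f"malformed variant id: {v.id!r}")
    if not v.contig:
        raise ReannotError(f"variant {v.id!r}: empty contig")
    return v


@dataclass(frozen=True, order=True)
class ExonInterval:
    """1-based inclusive exon span."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ReannotError(f"exon start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ReannotError(f"exon start {self.start} > end {self.end}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional genomic CDS span.

    Exons are stored in ascending genomic order for both strands; the CDS
    span is genomic (1-based inclusive) and, by this package's convention,
    includes the stop codon. A transcript is coding iff it has a CDS span.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[ExonInterval, ...]
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ReannotError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ReannotError(f"transcript {self.transcript_id!r}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ReannotError(
                    f"transcript {self.transcript_id!r}: exons overlap or are unsorted "
                    f"({a.start}-{a.end} then {b.start}-{b.end})"
                )
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if cs > ce:
                raise ReannotError(
                    f"transcript {self.transcript_id!r}: CDS start {cs} > end {ce}"
                )
            if not any(cs in e for e in self.exons) or not any(ce in e for e in self.exons):
                raise ReannotError(
                    f"transcript {self.transcript_id!r}: CDS span {cs}-{ce} not within exons"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    @property
    def start(self) -> int:
        """5'-most genomic coordinate of the footprint (leftmost base)."""
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Transcription start site: 5'-most coordinate on the transcript strand."""
        return self.start if self.strand == "+" else self.end

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in ascending order."""
        if self.cds_span is None:
            return []
        cs, ce = self.cds_span
        out: list[int] = []
        for exon in self.exons:
            lo, hi = max(exon.start, cs), min(exon.end, ce)
            if lo <= hi:
                out.extend(range(lo, hi + 1))
        return out


@dataclass(frozen=True)
class AnnotationSet:
    """A named collection of transcript models (one database)."""

    name: str
    transcripts: tuple[TranscriptModel, ...]
    role: str = "alternative"

    def __post_init__(self) -> None:
        if self.role not in ("baseline", "alternative"):
            raise ReannotError(f"annotation set {self.name!r}: bad role {self.role!r}")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        seen: set[str] = set()
        for tx in self.transcripts:
            if tx.transcript_id in seen:
                raise ReannotError(
                    f"annotation set {self.name!r}: duplicate transcript id {tx.transcript_id!r}"
                )
            seen.add(tx.transcript_id)

    def coding_genes(self) -> frozenset[str]:
        """Genes with at least one protein-coding isoform."""
        return frozenset(tx.gene_id for tx in self.transcripts if tx.is_coding)

    def by_contig(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts:
            out.setdefault(tx.contig, []).append(tx)
        return out


@dataclass(frozen=True)
class CodingConsequence:
    """Codon-level effect of a SNV inside a CDS.

    ``ref_mismatch`` flags a variant whose declared reference allele
    disagrees with the genome base; the genome base defines the reference
    codon in that case.
    """

    kind: ConsequenceKind
    transcript_id: Optional[str] = None
    codon_index: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    ref_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.codon_index is not None and self.codon_index < 1:
            raise ReannotError(f"codon_index must be >= 1, got {self.codon_index}")
        k = self.kind
        ra, aa = self.ref_aa, self.alt_aa
        if ra is not None and aa is not None:
            if k is ConsequenceKind.SYNONYMOUS and ra != aa:
                raise ReannotError("SYNONYMOUS requires ref_aa == alt_aa")
            if k is ConsequenceKind.STOPGAIN and not (ra != STOP_AA and aa == STOP_AA):
                raise ReannotError("STOPGAIN requires non-stop ref_aa and stop alt_aa")
            if k is ConsequenceKind.STOPLOSS and not (ra == STOP_AA and aa != STOP_AA):
                raise ReannotError("STOPLOSS requires stop ref_aa and non-stop alt_aa")
            if k is ConsequenceKind.NONSYNONYMOUS and (
                ra == aa or ra == STOP_AA or aa == STOP_AA
            ):
                raise ReannotError("NONSYNONYMOUS requires distinct non-stop amino acids")
        elif k is not ConsequenceKind.UNKNOWN:
            raise ReannotError(f"{k.value} requires ref_aa and alt_aa")


@dataclass(frozen=True)
class TranscriptCall:
    """Per-transcript category of one variant, plus consequence for CDS hits."""

    transcript_id: str
    gene_id: str
    category: RegionCategory
    consequence: Optional[CodingConsequence] = None


@dataclass(frozen=True)
class RegionCall:
    """Category of one variant under one annotation set.

    The top-level ``category`` is the highest-precedence category across
    transcripts; ``gene_ids`` lists every gene contributing that category,
    sorted lexicographically.
    """

    variant_id: str
    set_name: str
    category: RegionCategory
    gene_ids: tuple[str, ...] = ()
    transcript_calls: tuple[TranscriptCall, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "transcript_calls", tuple(self.transcript_calls))
        if self.transcript_calls:
            best = min(tc.category.precedence for tc in self.transcript_calls)
            if self.category.precedence != best:
                raise ReannotError(
                    f"call for {self.variant_id!r}/{self.set_name!r}: top-level category "
                    f"{self.category.value} is not the highest-precedence transcript category"
                )


#: Alternative-set categories that re-annotate a baseline-noncoding variant
#: regardless of the baseline category.
REANNOTATING_CATEGORIES = frozenset(
    {
        RegionCategory.CDS,
        RegionCategory.SPLICE,
        RegionCategory.UTR5,
        RegionCategory.UTR3,
        RegionCategory.NCRNA_EXONIC,
        RegionCategory.PROMOTER,
    }
)


def reannotates(baseline: RegionCategory, alt: RegionCategory) -> bool:
    """Whether an alternative-set category re-annotates a baseline category.

    A variant is re-annotatable only when the baseline calls it INTRONIC or
    INTERGENIC. Any exonic, splice, promoter or ncRNA category in an
    alternative set then counts; an alternative INTRONIC call counts only
    when the baseline was INTERGENIC (a gene exists where the baseline had
    none).
    """
    if baseline not in (RegionCategory.INTRONIC, RegionCategory.INTERGENIC):
        return False
    if alt in REANNOTATING_CATEGORIES:
        return True
    return alt is RegionCategory.INTRONIC and baseline is RegionCategory.INTERGENIC


@dataclass(frozen=True)
class ReannotationDelta:
    """Baseline vs alternative-set categories of one variant."""

    variant_id: str
    baseline_category: RegionCategory
    per_set_category: Mapping[str, RegionCategory]
    per_set_genes: Mapping[str, tuple[str, ...]]
    is_reannotated: bool
    coding_support: int
    reannotating_sets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        n_alt = len(self.per_set_category)
        if self.coding_support > n_alt:
            raise ReannotError(
                f"delta for {self.variant_id!r}: coding_support {self.coding_support} "
                f"exceeds number of alternative sets {n_alt}"
            )
        expect = any(
            reannotates(self.baseline_category, cat)
            for cat in self.per_set_category.values()
        )
        if expect != self.is_reannotated:
            raise ReannotError(
                f"delta for {self.variant_id!r}: is_reannotated inconsistent with categories"
            )


@dataclass(frozen=True)
class RegulatoryProfile:
    """Distinct regulatory feature classes overlapping one variant."""

    variant_id: str
    classes: frozenset[RegulatoryFeatureClass] = frozenset()

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class ExpressionRecord:
    """Point estimate (FPKM) and posterior SD of one gene in one tissue."""

    gene_id: str
    tissue: str
    estimate: float
    posterior_sd: float

    def __post_init__(self) -> None:
        if self.estimate < 0:
            raise ReannotError(
                f"expression of {self.gene_id!r}/{self.tissue!r}: negative estimate"
            )
        if self.posterior_sd < 0:
            raise ReannotError(
                f"expression of {self.gene_id!r}/{self.tissue!r}: negative posterior SD"
            )

    def is_expressed(self, thresholds: Thresholds) -> bool:
        """Expressed iff posterior SD strictly below the threshold."""
        return self.posterior_sd < thresholds.expression_sd_max


@dataclass(frozen=True)
class TrackFeature:
    """One interval of a regulatory track, kept in BED coordinates.

    ``start``/``end`` are 0-based half-open exactly as read; use
    :meth:`covers` for 1-based containment tests.
    """

    contig: str
    start: int
    end: int
    feature_class: RegulatoryFeatureClass
    source_track: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ReannotError(
                f"track feature {self.contig}:{self.start}-{self.end}: start must be < end"
            )

    def covers(self, contig: str, position: int) -> bool:
        """Containment of a 1-based position (BED start+1 .. end inclusive)."""
        return contig == self.contig and self.start + 1 <= position <= self.end
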