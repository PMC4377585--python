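"""Deterministic synthetic fixtures with full ground truth.

Generates a small genome, one baseline plus several alternative
annotation sets that disagree in controlled ways, a variant list with
planted categories and coding consequences, regulatory-feature tracks and
a gene x tissue expression table. Three discordance mechanisms are
modelled, matching how real annotation databases diverge:

* ``missing_exon`` — the baseline transcript lacks one internal exon that
  alternative sets include, so a variant in that exon is intronic under
  the baseline but coding under the alternatives;
* ``alt_only`` — a gene entirely absent from the baseline, so variants in
  its promoter, UTRs, CDS, introns or ncRNA exons are intergenic under
  the baseline;
* ``cds_extension`` — the alternative CDS extends past the baseline stop,
  turning baseline-UTR positions into alternative-CDS positions.

All randomness flows from the single seed; identical specs produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as rio
from .models import (
    AnnotationSet,
    ConsequenceKind,
    ExonInterval,
    ExpressionRecord,
    ReannotError,
    RegionCategory,
    RegulatoryFeatureClass,
    Thresholds,
    TrackFeature,
    TranscriptModel,
    Variant,
    reannotates,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Non-stop codons used to fill coding bodies.
_BODY_CODONS = ("GCC", "GAT", "CTG", "AAA", "TCC", "GGA", "TTC", "CAG")

DEFAULT_TISSUES = (
    "adipose",
    "adrenal",
    "brain",
    "breast",
    "colon",
    "heart",
    "kidney",
    "liver",
    "lung",
    "lymph_node",
    "ovary",
    "prostate",
    "skeletal_muscle",
    "testis",
    "thyroid",
    "white_blood_cells",
)


class FixturePlanError(ReannotError):
    """The requested planted counts are not achievable on the gene layout."""


@dataclass(frozen=True)
class FixtureSpec:
    """Study-condition plan for one synthetic fixture.

    Defaults give 3 alternative annotation sets over one ~100 kb contig
    with ~15 genes and ~45 planted variants covering every category,
    delta pattern and consequence kind.
    """

    seed: int = 0
    contig: str = "chrS"
    alt_set_names: tuple[str, ...] = ("altA", "altB", "altC")
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    gene_pitch: int = 3000
    # gene counts per discordance mechanism
    n_shared_coding: int = 4
    n_shared_noncoding: int = 1
    n_missing_exon: int = 3
    n_cds_extension: int = 1
    n_alt_only_coding: int = 4
    n_alt_only_noncoding: int = 2
    # baseline-exonic variants (removed by the noncoding filter)
    n_baseline_cds: int = 3
    n_baseline_utr5: int = 2
    n_baseline_utr3: int = 2
    n_baseline_splice: int = 2
    # retained variants without re-annotation
    n_baseline_intronic: int = 3
    n_baseline_ncrna: int = 2
    n_intergenic: int = 4
    # intronic -> CDS deltas with planted consequence kinds
    n_syn: int = 3
    n_nonsyn: int = 3
    n_stopgain: int = 1
    n_unknown_coding: int = 2
    # intergenic -> X deltas in alt-only genes
    n_alt_cds_nonsyn: int = 2
    n_stoploss: int = 1
    n_alt_utr5: int = 2
    n_alt_utr3: int = 2
    n_alt_splice: int = 2
    n_alt_intronic: int = 2
    n_alt_promoter: int = 2
    n_alt_ncrna: int = 2
    # regulatory tracks
    n_decoy_features_per_class: int = 4

    def validate(self) -> None:
        n_cons = self.n_syn + self.n_nonsyn + self.n_stopgain + self.n_unknown_coding
        if n_cons > 10 * self.n_missing_exon:
            raise FixturePlanError(
                f"{n_cons} consequence variants requested but only "
                f"{10 * self.n_missing_exon} internal-exon codon slots available"
            )
        if self.n_stoploss > self.n_alt_only_coding:
            raise FixturePlanError(
                f"{self.n_stoploss} stop-loss variants requested but only "
                f"{self.n_alt_only_coding} stop codons placed in alternative-only genes"
            )
        if self.n_alt_cds_nonsyn > 5 * self.n_alt_only_coding:
            raise FixturePlanError("too many alternative-only CDS variants requested")
        for label, n, cap in (
            ("baseline CDS", self.n_baseline_cds, 3 * self.n_shared_coding),
            ("baseline UTR5", self.n_baseline_utr5, self.n_shared_coding),
            ("baseline UTR3", self.n_baseline_utr3, self.n_shared_coding),
            ("baseline splice", self.n_baseline_splice, self.n_shared_coding),
            ("baseline intronic", self.n_baseline_intronic, self.n_shared_coding),
            ("baseline ncRNA", self.n_baseline_ncrna, 3 * self.n_shared_noncoding),
            ("alt UTR5", self.n_alt_utr5, self.n_alt_only_coding),
            ("alt UTR3", self.n_alt_utr3, self.n_alt_only_coding),
            ("alt splice", self.n_alt_splice, self.n_alt_only_coding),
            ("alt intronic", self.n_alt_intronic, self.n_alt_only_coding),
            ("alt promoter", self.n_alt_promoter, self.n_alt_only_coding),
            ("alt ncRNA", self.n_alt_ncrna, 3 * self.n_alt_only_noncoding),
        ):
            if n > cap:
                raise FixturePlanError(
                    f"{n} {label} variants requested but layout capacity is {cap}"
                )


@dataclass(frozen=True)
class PlantedVariant:
    variant: Variant
    baseline_category: RegionCategory
    removed: bool
    per_set_category: dict[str, RegionCategory]
    gene_id: Optional[str] = None
    consequence_kind: Optional[ConsequenceKind] = None
    regulatory_classes: frozenset[RegulatoryFeatureClass] = frozenset()

    @property
    def is_reannotated(self) -> bool:
        return any(
            reannotates(self.baseline_category, cat)
            for cat in self.per_set_category.values()
        )

    @property
    def reannotating_sets(self) -> frozenset[str]:
        return frozenset(
            s
            for s, cat in self.per_set_category.items()
            if reannotates(self.baseline_category, cat)
        )

    @property
    def coding_sets(self) -> frozenset[str]:
        return frozenset(
            s for s, cat in self.per_set_category.items() if cat is RegionCategory.CDS
        )


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    kind: str
    strand: str
    present_in: frozenset[str]  # set names, baseline included when present
    expressed_tissues: frozenset[str]

    @property
    def expressed(self) -> bool:
        return len(self.expressed_tissues) >= 1

    @property
    def tissue_specific(self) -> bool:
        return len(self.expressed_tissues) == 1


@dataclass(frozen=True)
class GroundTruth:
    """Expected labels for every generated variant and gene."""

    variants: dict[str, PlantedVariant]
    genes: dict[str, PlantedGene]

    def expected_union(self) -> set[str]:
        return {vid for vid, pv in self.variants.items() if not pv.removed and pv.is_reannotated}

    def expected_breakdown(self) -> dict[ConsequenceKind, int]:
        out = {k: 0 for k in ConsequenceKind}
        for pv in self.variants.values():
            if not pv.removed and pv.coding_sets and pv.consequence_kind is not None:
                out[pv.consequence_kind] += 1
        return out

    def expected_expressed_summary(self) -> dict[str, tuple[int, int]]:
        """Per alternative set: (expressed variant-harboring genes, variants)."""
        per_set: dict[str, dict[str, set[str]]] = {}
        all_sets: set[str] = set()
        for pv in self.variants.values():
            all_sets |= set(pv.per_set_category)
        for s in all_sets:
            per_set[s] = {}
        for vid, pv in self.variants.items():
            if pv.removed:
                continue
            for s in pv.reannotating_sets:
                if pv.gene_id is not None:
                    per_set[s].setdefault(pv.gene_id, set()).add(vid)
        summary = {}
        for s, genes in per_set.items():
            expressed = {
                g: vs for g, vs in genes.items() if self.genes[g].expressed
            }
            variants: set[str] = set()
            for vs in expressed.values():
                variants |= vs
            summary[s] = (len(expressed), len(variants))
        return summary


@dataclass
class Fixture:
    """Paths to the generated files plus the in-memory ground truth."""

    out_dir: Path
    spec: FixtureSpec
    manifest: dict
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# gene construction


@dataclass
class _Gene:
    gene_id: str
    kind: str
    strand: str
    start: int  # genomic start of the footprint
    exon_lens_t: tuple[int, ...]  # transcript order
    intron_lens_t: tuple[int, ...]
    utr5: int
    cds_len: int  # 0 for noncoding
    mask: frozenset[str]  # alternative sets carrying the full structure
    seq_t: list[str] = field(default_factory=list)  # transcript-strand bases

    @property
    def total(self) -> int:
        return sum(self.exon_lens_t)

    def _genomic_exons(self, exon_lens_t: Sequence[int], intron_lens_t: Sequence[int]) -> list[ExonInterval]:
        lens = list(exon_lens_t) if self.strand == "+" else list(exon_lens_t)[::-1]
        gaps = list(intron_lens_t) if self.strand == "+" else list(intron_lens_t)[::-1]
        out = []
        cur = self.start
        for i, L in enumerate(lens):
            out.append(ExonInterval(cur, cur + L - 1))
            cur += L + (gaps[i] if i < len(gaps) else 0)
        return out

    @property
    def exons_g(self) -> list[ExonInterval]:
        return self._genomic_exons(self.exon_lens_t, self.intron_lens_t)

    @property
    def pos_list(self) -> list[int]:
        return [p for e in self.exons_g for p in range(e.start, e.end + 1)]

    def t2g(self, offset: int) -> int:
        """Genomic position of a transcript-strand offset."""
        pl = self.pos_list
        return pl[offset] if self.strand == "+" else pl[len(pl) - 1 - offset]

    def cds_span_g(self, cds_len: Optional[int] = None) -> Optional[tuple[int, int]]:
        L = self.cds_len if cds_len is None else cds_len
        if L == 0:
            return None
        a, b = self.t2g(self.utr5), self.t2g(self.utr5 + L - 1)
        return (min(a, b), max(a, b))

    def transcript(self, suffix: str = "t1", cds_len: Optional[int] = None,
                   drop_transcript_exon: Optional[int] = None) -> TranscriptModel:
        exons = self.exons_g
        if drop_transcript_exon is not None:
            g_idx = (
                drop_transcript_exon
                if self.strand == "+"
                else len(exons) - 1 - drop_transcript_exon
            )
            exons = [e for i, e in enumerate(exons) if i != g_idx]
        return TranscriptModel(
            transcript_id=f"{self.gene_id}.{suffix}",
            gene_id=self.gene_id,
            contig="",  # filled by caller
            strand=self.strand,
            exons=tuple(exons),
            cds_span=self.cds_span_g(cds_len),
        )


def _fill_genome(genome: list[str], gene: _Gene) -> None:
    t = "".join(gene.seq_t)
    seq = t if gene.strand == "+" else t.translate(_COMPLEMENT)[::-1]
    for base, pos in zip(seq, gene.pos_list):
        genome[pos - 1] = base


def _design_transcript_seq(gene: _Gene, rng: np.random.Generator) -> None:
    """Random UTRs, ATG...stop CDS filled with non-stop body codons."""
    bases = "ACGT"
    seq = [bases[i] for i in rng.integers(0, 4, size=gene.total)]
    if gene.cds_len:
        n_codons = gene.cds_len // 3
        codons = ["ATG"] + [
            _BODY_CODONS[i] for i in rng.integers(0, len(_BODY_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        cds = "".join(codons)
        for i, b in enumerate(cds):
            seq[gene.utr5 + i] = b
    gene.seq_t = seq


# ---------------------------------------------------------------------------
# generator


def generate_fixture(spec: FixtureSpec, out_dir) -> Fixture:
    """Write all fixture files under ``out_dir`` and return the ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alt_names = spec.alt_set_names
    margin = 2000
    pitch = spec.gene_pitch

    # --- lay out genes -----------------------------------------------------
    genes: list[_Gene] = []
    kinds = (
        ["shared_coding"] * spec.n_shared_coding
        + ["shared_noncoding"] * spec.n_shared_noncoding
        + ["missing_exon"] * spec.n_missing_exon
        + ["cds_extension"] * spec.n_cds_extension
        + ["alt_only_coding"] * spec.n_alt_only_coding
        + ["alt_only_noncoding"] * spec.n_alt_only_noncoding
    )
    missing_exon_masks = [
        frozenset(alt_names),
        frozenset(alt_names[:1]),
        frozenset(alt_names[:2]),
    ]
    alt_only_masks = [
        frozenset(alt_names),
        frozenset(alt_names[1:2]) or frozenset(alt_names[:1]),
        frozenset(alt_names[-1:]),
        frozenset(alt_names[:2]),
    ]
    counters: dict[str, int] = {}
    for i, kind in enumerate(kinds):
        j = counters.get(kind, 0)
        counters[kind] = j + 1
        strand = "+" if (i % 2 == 0) else "-"
        start = margin + i * pitch
        if kind in ("shared_coding", "shared_noncoding", "missing_exon", "cds_extension"):
            mask = frozenset(alt_names)
            if kind == "missing_exon":
                mask = missing_exon_masks[j % len(missing_exon_masks)]
        else:
            mask = alt_only_masks[j % len(alt_only_masks)]
        if kind in ("shared_coding", "cds_extension"):
            g = _Gene(f"g_{kind}_{j}", kind, strand, start, (30, 30), (40,), 12, 36, mask)
        elif kind == "shared_noncoding":
            g = _Gene(f"g_{kind}_{j}", kind, strand, start, (40,), (), 0, 0, mask)
        elif kind == "missing_exon":
            g = _Gene(f"g_{kind}_{j}", kind, strand, start, (33, 30, 33), (60, 60), 12, 72, mask)
        elif kind == "alt_only_coding":
            g = _Gene(f"g_{kind}_{j}", kind, strand, start, (36, 36), (50,), 12, 48, mask)
        else:
            g = _Gene(f"g_{kind}_{j}", kind, strand, start, (40,), (), 0, 0, mask)
        if kind == "cds_extension":
            g.cds_len = 48  # full (alternative) CDS; baseline keeps 24
            g.exon_lens_t = (36, 36)
        _design_transcript_seq(g, rng)
        genes.append(g)

    intergenic_zone = margin + len(genes) * pitch
    decoy_zone = intergenic_zone + spec.n_intergenic * 500 + 2000
    contig_length = decoy_zone + 7 * (spec.n_decoy_features_per_class * 120) + margin

    genome = [  # background then gene overwrites
        "ACGT"[i] for i in rng.integers(0, 4, size=contig_length)
    ]
    for g in genes:
        _fill_genome(genome, g)
    genome_str = "".join(genome)

    # --- plant variants ----------------------------------------------------
    planted: list[PlantedVariant] = []
    vid_counter = [1000]
    traits = ("height", "type 2 diabetes", "eosinophil count", "cholesterol", "asthma")

    def comp(b: str) -> str:
        return b.translate(_COMPLEMENT)

    def new_variant(
        pos: int,
        ref_t: Optional[str],
        alt_t: Optional[str],
        strand: str,
        *,
        genomic_alleles: bool = False,
    ) -> Variant:
        vid = f"rs{vid_counter[0]}"
        vid_counter[0] += 1
        if genomic_alleles or strand == "+":
            ref_g, alt_g = ref_t, alt_t
        else:
            ref_g = comp(ref_t) if ref_t else None
            alt_g = comp(alt_t) if alt_t else None
        if ref_g is not None:
            assert genome_str[pos - 1] == ref_g, "planted ref disagrees with genome"
        return Variant(
            id=vid,
            contig=spec.contig,
            position=pos,
            ref_allele=ref_g,
            alt_allele=alt_g,
            trait=traits[vid_counter[0] % len(traits)],
        )

    def other_base(b: str) -> str:
        return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]

    def plant(
        gene: Optional[_Gene],
        pos: int,
        ref_t: Optional[str],
        alt_t: Optional[str],
        baseline_cat: RegionCategory,
        removed: bool,
        alt_cat_in_mask: Optional[RegionCategory],
        alt_cat_outside: RegionCategory,
        kind: Optional[ConsequenceKind] = None,
        genomic_alleles: bool = False,
    ) -> None:
        strand = gene.strand if gene else "+"
        v = new_variant(pos, ref_t, alt_t, strand, genomic_alleles=genomic_alleles)
        per_set = {
            s: (alt_cat_in_mask if (gene and s in gene.mask) else alt_cat_outside)
            for s in alt_names
        }
        planted.append(
            PlantedVariant(
                variant=v,
                baseline_category=baseline_cat,
                removed=removed,
                per_set_category=per_set,
                gene_id=gene.gene_id if gene else None,
                consequence_kind=kind,
            )
        )

    shared = [g for g in genes if g.kind == "shared_coding"]
    shared_nc = [g for g in genes if g.kind == "shared_noncoding"]
    mex = [g for g in genes if g.kind == "missing_exon"]
    cext = [g for g in genes if g.kind == "cds_extension"]
    aoc = [g for g in genes if g.kind == "alt_only_coding"]
    aon = [g for g in genes if g.kind == "alt_only_noncoding"]

    # baseline-exonic (removed) variants in shared coding genes
    for i in range(spec.n_baseline_cds):
        g = shared[i % len(shared)]
        codon = 2 + 3 * (i // len(shared))  # codon slots 2, 5, 8
        off = g.utr5 + 3 * codon + 1
        ref = g.seq_t[off]
        plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.CDS, True,
              RegionCategory.CDS, RegionCategory.CDS)
    for i in range(spec.n_baseline_utr5):
        g = shared[i % len(shared)]
        off = 5
        ref = g.seq_t[off]
        plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.UTR5, True,
              RegionCategory.UTR5, RegionCategory.UTR5)
    for i in range(spec.n_baseline_utr3):
        g = shared[(i + 1) % len(shared)]
        off = g.total - 6
        ref = g.seq_t[off]
        plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.UTR3, True,
              RegionCategory.UTR3, RegionCategory.UTR3)
    for i in range(spec.n_baseline_splice):
        g = shared[(i + 2) % len(shared)]
        pos = g.exons_g[0].end + 1  # 1 bp into the intron
        ref = genome_str[pos - 1]
        plant(g, pos, ref, other_base(ref), RegionCategory.SPLICE, True,
              RegionCategory.SPLICE, RegionCategory.SPLICE, genomic_alleles=True)
    # cds-extension variants: baseline UTR3, alternatives CDS (removed anyway)
    for i, g in enumerate(cext):
        off = g.utr5 + 30  # inside the extended CDS half, past baseline stop
        ref = g.seq_t[off]
        plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.UTR3, True,
              RegionCategory.CDS, RegionCategory.CDS)

    # retained, never re-annotated
    for i in range(spec.n_baseline_intronic):
        g = shared[i % len(shared)]
        pos = g.exons_g[0].end + 15 + i // len(shared)
        ref = genome_str[pos - 1]
        plant(g, pos, ref, other_base(ref), RegionCategory.INTRONIC, False,
              RegionCategory.INTRONIC, RegionCategory.INTRONIC, genomic_alleles=True)
    for i in range(spec.n_baseline_ncrna):
        g = shared_nc[i % len(shared_nc)]
        off = 10 + 4 * i
        ref = g.seq_t[off]
        plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.NCRNA_EXONIC, False,
              RegionCategory.NCRNA_EXONIC, RegionCategory.NCRNA_EXONIC)
    for i in range(spec.n_intergenic):
        pos = intergenic_zone + 500 * i + 250
        ref = genome_str[pos - 1]
        plant(None, pos, ref, other_base(ref), RegionCategory.INTERGENIC, False,
              None, RegionCategory.INTERGENIC, genomic_alleles=True)

    # intronic -> CDS deltas with designed consequences (missing-exon genes)
    cons_plan = (
        [(ConsequenceKind.SYNONYMOUS, "GCC", 2, "C", "A")] * spec.n_syn
        + [(ConsequenceKind.NONSYNONYMOUS, "GCC", 0, "G", "T")] * spec.n_nonsyn
        + [(ConsequenceKind.STOPGAIN, "TGG", 2, "G", "A")] * spec.n_stopgain
        + [(ConsequenceKind.UNKNOWN, "GAT", 1, "A", None)] * spec.n_unknown_coding
    )
    slot = {g.gene_id: 7 for g in mex}  # codons 7..16 lie inside the middle exon
    for i, (kind, codon, within, ref_t, alt_t) in enumerate(cons_plan):
        g = mex[i % len(mex)]
        k = slot[g.gene_id]
        slot[g.gene_id] += 1
        base_off = g.utr5 + 3 * k
        for w, b in enumerate(codon):  # write the designed codon
            g.seq_t[base_off + w] = b
        _fill_genome(genome, g)
        genome_str = "".join(genome)
        off = base_off + within
        plant(g, g.t2g(off), ref_t, alt_t, RegionCategory.INTRONIC, False,
              RegionCategory.CDS, RegionCategory.INTRONIC, kind=kind)

    # intergenic -> X deltas in alternative-only genes
    aoc_slot = {g.gene_id: 2 for g in aoc}  # free codons 2..6 for CDS variants
    for i in range(spec.n_alt_cds_nonsyn):
        g = aoc[i % len(aoc)]
        k = aoc_slot[g.gene_id]
        aoc_slot[g.gene_id] += 1
        base_off = g.utr5 + 3 * k
        for w, b in enumerate("GCC"):
            g.seq_t[base_off + w] = b
        _fill_genome(genome, g)
        genome_str = "".join(genome)
        plant(g, g.t2g(base_off), "G", "T", RegionCategory.INTERGENIC, False,
              RegionCategory.CDS, RegionCategory.INTERGENIC,
              kind=ConsequenceKind.NONSYNONYMOUS)
    for i in range(spec.n_stoploss):
        g = aoc[-(i + 1)]
        off = g.utr5 + g.cds_len - 3  # first base of the terminal TAA
        plant(g, g.t2g(off), "T", "C", RegionCategory.INTERGENIC, False,
              RegionCategory.CDS, RegionCategory.INTERGENIC,
              kind=ConsequenceKind.STOPLOSS)
    for n, cat, off_fn in (
        (spec.n_alt_utr5, RegionCategory.UTR5, lambda g: 5),
        (spec.n_alt_utr3, RegionCategory.UTR3, lambda g: g.total - 5),
    ):
        for i in range(n):
            g = aoc[i % len(aoc)]
            off = off_fn(g)
            ref = g.seq_t[off]
            plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.INTERGENIC,
                  False, cat, RegionCategory.INTERGENIC)
    for i in range(spec.n_alt_splice):
        g = aoc[(i + 1) % len(aoc)]
        pos = g.exons_g[0].end + 2  # exactly at the 2 bp splice-window edge
        ref = genome_str[pos - 1]
        plant(g, pos, ref, other_base(ref), RegionCategory.INTERGENIC, False,
              RegionCategory.SPLICE, RegionCategory.INTERGENIC, genomic_alleles=True)
    for i in range(spec.n_alt_intronic):
        g = aoc[(i + 2) % len(aoc)]
        pos = g.exons_g[0].end + 20 + i // len(aoc)
        ref = genome_str[pos - 1]
        plant(g, pos, ref, other_base(ref), RegionCategory.INTERGENIC, False,
              RegionCategory.INTRONIC, RegionCategory.INTERGENIC, genomic_alleles=True)
    for i in range(spec.n_alt_promoter):
        g = aoc[(i + 3) % len(aoc)]
        tss = g.exons_g[0].start if g.strand == "+" else g.exons_g[-1].end
        pos = tss - 50 - i if g.strand == "+" else tss + 50 + i
        ref = genome_str[pos - 1]
        plant(g, pos, ref, other_base(ref), RegionCategory.INTERGENIC, False,
              RegionCategory.PROMOTER, RegionCategory.INTERGENIC, genomic_alleles=True)
    for i in range(spec.n_alt_ncrna):
        g = aon[i % len(aon)]
        off = 15 + 3 * i
        ref = g.seq_t[off]
        plant(g, g.t2g(off), ref, other_base(ref), RegionCategory.INTERGENIC, False,
              RegionCategory.NCRNA_EXONIC, RegionCategory.INTERGENIC)

    genome_str = "".join(genome)
    variant_positions = {pv.variant.position for pv in planted}
    if len(variant_positions) != len(planted):
        raise FixturePlanError("planted variant positions collide")

    # --- regulatory tracks -------------------------------------------------
    classes = list(RegulatoryFeatureClass)
    features: list[TrackFeature] = []
    planted2: list[PlantedVariant] = []
    for pv in planted:
        k = int(rng.choice([0, 1, 2, 3], p=[0.25, 0.35, 0.25, 0.15]))
        chosen = sorted(
            (classes[j] for j in rng.choice(len(classes), size=k, replace=False)),
            key=lambda c: c.value,
        )
        pos = pv.variant.position
        for cls in chosen:
            ext_l, ext_r = int(rng.integers(0, 9)), int(rng.integers(0, 9))
            lo, hi = pos - ext_l, pos + ext_r
            if any(q in variant_positions for q in range(lo, hi + 1) if q != pos):
                lo = hi = pos  # keep ground truth exact near clustered variants
            features.append(
                TrackFeature(spec.contig, lo - 1, hi, cls, source_track=f"{cls.value}.bed")
            )
        planted2.append(
            PlantedVariant(
                variant=pv.variant,
                baseline_category=pv.baseline_category,
                removed=pv.removed,
                per_set_category=pv.per_set_category,
                gene_id=pv.gene_id,
                consequence_kind=pv.consequence_kind,
                regulatory_classes=frozenset(chosen),
            )
        )
    planted = planted2
    for ci, cls in enumerate(classes):
        for d in range(spec.n_decoy_features_per_class):
            lo = decoy_zone + (ci * spec.n_decoy_features_per_class + d) * 120 + int(
                rng.integers(0, 40)
            )
            features.append(
                TrackFeature(
                    spec.contig, lo, lo + 15 + int(rng.integers(0, 25)), cls,
                    source_track=f"{cls.value}.bed",
                )
            )

    # --- annotation sets ---------------------------------------------------
    def tx_for(gene: _Gene, set_name: str) -> Optional[TranscriptModel]:
        if set_name == "baseline":
            if gene.kind.startswith("alt_only"):
                return None
            if gene.kind == "missing_exon":
                tx = gene.transcript(drop_transcript_exon=1)
            elif gene.kind == "cds_extension":
                tx = gene.transcript(cds_len=24)
            else:
                tx = gene.transcript()
        else:
            if gene.kind == "missing_exon":
                tx = gene.transcript() if set_name in gene.mask else gene.transcript(
                    drop_transcript_exon=1
                )
            elif gene.kind.startswith("alt_only"):
                if set_name not in gene.mask:
                    return None
                tx = gene.transcript()
            else:
                tx = gene.transcript()
        return TranscriptModel(
            transcript_id=tx.transcript_id,
            gene_id=tx.gene_id,
            contig=spec.contig,
            strand=tx.strand,
            exons=tx.exons,
            cds_span=tx.cds_span,
        )

    sets: dict[str, AnnotationSet] = {}
    for set_name in ("baseline",) + tuple(alt_names):
        txs = [t for g in genes if (t := tx_for(g, set_name)) is not None]
        role = "baseline" if set_name == "baseline" else "alternative"
        sets[set_name] = AnnotationSet(name=set_name, transcripts=tuple(txs), role=role)

    # --- expression --------------------------------------------------------
    records: list[ExpressionRecord] = []
    gene_truth: dict[str, PlantedGene] = {}
    for g in genes:
        status = rng.choice(["none", "specific", "broad"], p=[0.2, 0.2, 0.6])
        if status == "none":
            expressed: tuple[str, ...] = ()
        elif status == "specific":
            expressed = (spec.tissues[int(rng.integers(0, len(spec.tissues)))],)
        else:
            m = int(rng.integers(2, len(spec.tissues) + 1))
            idx = rng.choice(len(spec.tissues), size=m, replace=False)
            expressed = tuple(spec.tissues[i] for i in sorted(idx))
        for tissue in spec.tissues:
            if tissue in expressed:
                est = float(rng.uniform(1, 100))
                sd = float(rng.uniform(0.1, 1.4))
            else:
                est = float(rng.uniform(0, 0.5))
                sd = float(rng.uniform(1.6, 3.0))
            records.append(ExpressionRecord(g.gene_id, tissue, round(est, 4), round(sd, 4)))
        present = set()
        if not g.kind.startswith("alt_only"):
            present.add("baseline")
        present |= set(g.mask) if g.kind.startswith("alt_only") else set(alt_names)
        gene_truth[g.gene_id] = PlantedGene(
            gene_id=g.gene_id,
            kind=g.kind,
            strand=g.strand,
            present_in=frozenset(present),
            expressed_tissues=frozenset(expressed),
        )

    # --- write files -------------------------------------------------------
    rio.write_fasta({spec.contig: genome_str}, out_dir / "genome.fa")
    dialects = {}
    for set_name, aset in sets.items():
        # exercise both gene-model dialects: one alternative set ships as genePred
        if len(alt_names) > 1 and set_name == alt_names[1]:
            path = out_dir / f"{set_name}.genePred"
            rio.write_genepred(aset, path)
            dialects[set_name] = ("genepred", path.name)
        else:
            path = out_dir / f"{set_name}.gtf"
            rio.write_gtf(aset, path)
            dialects[set_name] = ("gtf", path.name)
    variants = [pv.variant for pv in planted]
    rio.write_variants_tsv(variants, out_dir / "variants.tsv")
    rio.write_variants_vcf(
        variants, out_dir / "variants.vcf", {spec.contig: contig_length}
    )
    track_files = {}
    for cls in classes:
        cls_feats = [f for f in features if f.feature_class is cls]
        path = out_dir / f"track_{cls.value}.bed"
        rio.write_track_bed(cls_feats, path)
        track_files[cls.value] = path.name
    rio.write_expression_tsv(records, out_dir / "expression.tsv")

    manifest = {
        "seed": spec.seed,
        "contig": spec.contig,
        "contig_length": contig_length,
        "genome": "genome.fa",
        "variants_tsv": "variants.tsv",
        "variants_vcf": "variants.vcf",
        "expression": "expression.tsv",
        "sets": [
            {
                "name": name,
                "path": dialects[name][1],
                "dialect": dialects[name][0],
                "role": sets[name].role,
            }
            for name in ("baseline",) + tuple(alt_names)
        ],
        "tracks": track_files,
        "thresholds": asdict(Thresholds()),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    truth = GroundTruth(
        variants={pv.variant.id: pv for pv in planted}, genes=gene_truth
    )
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return Fixture(out_dir=out_dir, spec=spec, manifest=manifest, ground_truth=truth)


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "variants": {
            vid: {
                "position": pv.variant.position,
                "baseline_category": pv.baseline_category.value,
                "removed": pv.removed,
                "per_set_category": {s: c.value for s, c in sorted(pv.per_set_category.items())},
                "gene_id": pv.gene_id,
                "consequence_kind": pv.consequence_kind.value if pv.consequence_kind else None,
                "regulatory_classes": sorted(c.value for c in pv.regulatory_classes),
                "is_reannotated": pv.is_reannotated,
            }
            for vid, pv in sorted(truth.variants.items())
        },
        "genes": {
            gid: {
                "kind": pg.kind,
                "strand": pg.strand,
                "present_in": sorted(pg.present_in),
                "expressed_tissues": sorted(pg.expressed_tissues),
            }
            for gid, pg in sorted(truth.genes.items())
        },
    }
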