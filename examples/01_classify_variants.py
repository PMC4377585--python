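"""Classify a handful of SNPs against a small hand-built gene annotation.

Builds one coding transcript in memory, classifies variants at
characteristic positions, and prints the functional category each one
receives. SPLICE marks intronic positions within 2 bp of an exon/intron
boundary; PROMOTER marks the 1 kb window upstream of the TSS.
"""

from reannot import (
    AnnotationSet,
    ExonInterval,
    TranscriptModel,
    Variant,
    classify_variant,
)

# Two-exon coding gene: exons 2001-2300 and 2601-2900, CDS 2101-2800.
tx = TranscriptModel(
    transcript_id="tx1",
    gene_id="geneA",
    contig="chr1",
    strand="+",
    exons=(ExonInterval(2001, 2300), ExonInterval(2601, 2900)),
    cds_span=(2101, 2800),
)
annotation = AnnotationSet(name="demo", transcripts=(tx,), role="alternative")

probes = [
    ("in the CDS", Variant("rs_cds", "chr1", 2200, "A", None)),
    ("in the 5' UTR", Variant("rs_utr5", "chr1", 2050)),
    ("2 bp into the intron", Variant("rs_splice", "chr1", 2302)),
    ("mid-intron", Variant("rs_intron", "chr1", 2450)),
    ("300 bp upstream of the TSS", Variant("rs_prom", "chr1", 1701)),
    ("far away", Variant("rs_far", "chr1", 9000)),
]

print(f"{'variant':12s} {'where':28s} category   genes")
for where, v in probes:
    call = classify_variant(v, annotation)
    print(f"{v.id:12s} {where:28s} {call.category.value:10s} {','.join(call.gene_ids)}")

# Each variant gets exactly one category per annotation set; coding and
# splice-window calls outrank UTR, intronic and promoter calls when
# several transcripts overlap a position.
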