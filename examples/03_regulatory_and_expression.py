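"""Regulatory-feature overlap and the expressed-gene criterion.

Overlaps variants with class-labelled BED tracks (eQTL, motif, DNase
footprint, ...) and applies the posterior-SD expression filter: a gene
counts as expressed in a tissue when the posterior standard deviation of
its expression estimate is below 1.5.
"""

from reannot import (
    ExpressionRecord,
    RegulatoryFeatureClass,
    TrackFeature,
    Variant,
    coverage_fraction,
    feature_count_distribution,
    flag_expressed,
    overlap_features,
    tissue_specific_genes,
)

F = RegulatoryFeatureClass
variants = [Variant(f"rs{i}", "chr1", pos) for i, pos in
            enumerate([150, 420, 700, 980, 1500])]
tracks = [
    TrackFeature("chr1", 100, 200, F.EQTL),            # covers rs0
    TrackFeature("chr1", 140, 160, F.MOTIF),           # covers rs0 too
    TrackFeature("chr1", 400, 430, F.DNASE_FOOTPRINT), # covers rs1
    TrackFeature("chr1", 950, 1000, F.CONSERVED),      # covers rs3
]

profiles = overlap_features(variants, tracks)
for v in variants:
    classes = sorted(c.value for c in profiles[v.id].classes)
    print(f"{v.id}: {classes or ['no regulatory evidence']}")
hist = feature_count_distribution(profiles)
print(f"feature-class histogram (k classes -> variants): {hist}")
print(f"coverage: {coverage_fraction(profiles):.0%} of variants hit >=1 class\n")

expression = [
    ExpressionRecord("geneA", "liver", 35.2, 0.3),   # expressed
    ExpressionRecord("geneA", "brain", 12.1, 0.9),   # expressed
    ExpressionRecord("geneB", "liver", 0.8, 1.49),   # expressed (just under 1.5)
    ExpressionRecord("geneB", "brain", 0.1, 2.4),    # not expressed
    ExpressionRecord("geneC", "liver", 0.05, 1.5),   # not expressed (not < 1.5)
]
pairs, genes = flag_expressed(expression)
print(f"expressed (gene, tissue) pairs: {sorted(pairs)}")
print(f"genes expressed in >=1 tissue:  {sorted(genes)}")
print(f"tissue-specific genes:          {sorted(tissue_specific_genes(expression))}")
# geneB is tissue-specific: expressed in exactly one of its tissues.
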