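# Methods

## Problem and model

`reannot` re-assesses single-nucleotide variants that a baseline gene
annotation (a RefSeq-like catalog) labels noncoding. The working model is
that annotation databases are samples from an incompletely known
transcriptome: each database has its own pipeline and therefore its own
exons, transcripts and genes. A variant's functional category is thus a
property of a *(variant, annotation set)* pair, not of the variant alone.
The method's unit of inference is the **re-annotation delta**: the change
in category between the baseline set and each alternative set.

Coordinates are 1-based inclusive everywhere inside the package; BED and
genePred inputs (0-based half-open) are converted at the I/O boundary only
(`internal_start = bed_start + 1`, `internal_end = bed_end`).

## Region classification

Per transcript, a position is:

* **CDS** — inside an exon and inside the transcript's genomic CDS span;
* **UTR5/UTR3** — exonic, outside the CDS span, sided on the *transcript*
  strand (5′ of the CDS start vs 3′ of the CDS end);
* **NCRNA_EXONIC** — exonic in a transcript without a CDS;
* **SPLICE** — intronic, within `splice_window_bp` (default 2) of the
  nearest exon boundary of a multi-exon transcript. Splice status is an
  intronic property: exonic bases near a boundary keep their exonic
  category, which is what makes "exonic regions and splice-boundary areas"
  two disjoint removal classes in the baseline filter;
* **INTRONIC** — any other position between the transcript's first and
  last exon;
* **PROMOTER** — within `promoter_window_bp` (default 1000) upstream of
  the TSS on the transcript strand: `[TSS-w, TSS-1]` on `+`,
  `[TSS+1, TSS+w]` on `-`, clamped to contig bounds when known.

The top-level category per annotation set is the most severe across
transcripts: `CDS > SPLICE > UTR5 > UTR3 > NCRNA_EXONIC > INTRONIC >
PROMOTER > INTERGENIC`. This ordering follows the severity convention of
gene-based annotators; two of its consequences are deliberate design
choices: an intragenic call in one gene always beats a promoter call from
a neighboring gene (upstream never outranks inside-a-gene), and all genes
contributing the winning category are reported, sorted lexicographically,
so results are independent of transcript input order.

The baseline filter removes variants whose baseline category is CDS, UTR5,
UTR3 (exonic regions of protein-coding genes — a gene is protein-coding
iff it has ≥ 1 coding isoform) or SPLICE. In the full pipeline the
baseline pass runs with the PROMOTER category disabled (upstream positions
fall back to INTERGENIC): promoter windows are only credited during
re-annotation against the alternative sets. This asymmetry mirrors how
baseline-style annotation distinguishes only genic from intergenic; it is
a flag (`baseline_use_promoter`), not a constant.

## Re-annotation rule

A variant is re-annotated iff its baseline category is INTRONIC or
INTERGENIC and at least one alternative set assigns PROMOTER, CDS, UTR5,
UTR3, SPLICE or NCRNA_EXONIC — or INTRONIC when the baseline was
INTERGENIC (a gene exists where the baseline had none). Alternative
intronic over baseline intronic is *not* a re-annotation. The union counts
each variant once regardless of how many sets or categories rescue it
(set semantics); per-set memberships are always emitted so
intersection-style reporting can be reconstructed.

`coding_support` counts the alternative sets whose top-level category is
CDS; the consequence breakdown tabulates variants with support ≥ 1 by the
most severe consequence across all supporting transcripts.

## Coding consequences

The CDS is assembled by concatenating exonic CDS bases 5′→3′ on the
transcript strand (reverse-complemented for minus-strand transcripts),
giving a bijection between CDS genomic positions and 0-based offsets.
Codon index = offset÷3 + 1. The alternative allele is complemented for
minus-strand transcripts; translation uses the standard genetic code
(table 1) only. Kinds:

* STOPGAIN: ref amino acid ≠ stop, alt = stop;
* STOPLOSS: ref = stop, alt ≠ stop;
* SYNONYMOUS: ref = alt (this includes the rare stop-retained change,
  stop→stop, which is classed with synonymous as in the Sequence
  Ontology, and the degenerate alt-equals-reference case);
* NONSYNONYMOUS: everything else, including start-codon disruption;
* UNKNOWN: the alternative allele is unavailable, or the variant falls in
  a trailing partial codon of a CDS whose length is not a multiple of 3.

By package convention the CDS span includes the stop codon, so stop-loss
at the terminal codon is directly callable. If the declared reference
allele disagrees with the genome base, the genome base defines the
reference codon and the call carries a `ref_mismatch` flag — catalogs
often report risk alleles that equal the reference, or alleles from the
opposite strand, and the consequence must stay well-defined on such
inputs. Alleles are used as given; no strand-flipping heuristic is
applied. Severity for per-variant summaries: stop-gain = stop-loss >
non-synonymous > synonymous > unknown, ties broken by transcript id.

## Regulatory overlap and expression

Regulatory evidence (promoter/enhancer, motif, DNase footprint, eQTL,
conserved element, TFBS, ChIP-seq protein binding) is consumed as
class-labelled BED tracks rather than live database queries, making the
overlap computation reproducible offline. Profiles record *distinct*
classes per variant — two tracks of the same class count once — and the
k-distribution histogram conserves mass (Σ counts = N). Per-class counts
with multiplicity are also emitted, since bar-chart-style summaries can be
read either way.

Expression estimates (FPKM point estimate + posterior SD per gene per
tissue) come from an upstream quantification pipeline and are never
computed here. A gene is expressed in a tissue iff posterior SD <
`expression_sd_max` (strictly; 1.5 exactly is *not* expressed). The
threshold is applied to the SD column as provided, without a log
transform. "Tissue-specific" is operationalised as expressed in exactly
one tissue — the underlying claim is qualitative, so the definition is a
documented, overridable choice. Genes harboring re-annotated variants in a
set are those the set's own region call attributed the category to; genes
missing from the expression table are treated as not expressed and
logged.

## Synthetic fixtures

The generator emulates the method's study conditions at desk scale: one
~100 kb contig, one baseline plus three alternative annotation sets,
~15 genes and ~43 variants, seven regulatory track classes and a 16-tissue
expression table. Database discordance is modelled with the three
mechanisms observed in real multi-database comparisons — an internal exon
missing from the baseline, a gene entirely absent from the baseline, and a
CDS extended in the alternatives — which together exercise every delta
category (coding, UTR, splice, ncRNA, intronic-over-intergenic,
promoter). Consequence variants are planted by writing designed codons
(e.g. GCC for a third-position synonymous change, TGG for stop-gain, the
terminal TAA for stop-loss) into the genome and recording the exact
substitution. Expression is planted per gene as not-expressed /
tissue-specific / broadly expressed, with posterior SDs drawn strictly on
the intended side of the 1.5 cutoff. One alternative set is written as
genePred and the rest as GTF so both dialects are exercised end to end.

What the fixtures do **not** emulate: real sequence composition, overlap
of neighboring genes, alternative isoforms within a gene, indels,
multi-allelic sites, LD structure, or realistic genome-wide category
frequencies. Passing the planted-truth tests therefore demonstrates the
correctness of the classification/integration logic on controlled
discordance patterns, not calibration against any real catalog; the
published headline counts depend on specific 2013–2015 database versions
and are reproduced only as arithmetic-consistency checks on the printed
numbers.

## Numerical and degenerate-input choices

* All randomness in the generator flows from one integer seed
  (`numpy.random.default_rng`); identical specs give byte-identical files.
* Variants are strictly single-nucleotide; indel rows are skipped with a
  warning at I/O and rejected at construction.
* Duplicate variant identifiers keep the first occurrence (count logged);
  rows without an identifier are rejected.
* A variant on a contig absent from an annotation set is INTERGENIC (with
  a warning), not an error: catalogs routinely contain contigs a given
  database lacks.
* Degenerate BED intervals (start ≥ end) and negative expression values
  are rejected row-wise; a duplicated (gene, tissue) pair is a hard error.
* Result writers emit deterministic row order (variant id, then set name)
  so repeated runs are byte-identical.
* Problem sizes in the test-suite oracles (hundreds of probe positions,
  five seeds, 576 codon substitutions) were chosen to enumerate the
  relevant case space exhaustively where finite and to sample it densely
  where not, while keeping the whole suite interactive.

## Known limitations

* No GFF3, bgzip/tabix, or remote database access; no downstream
  (3′-of-gene) category and no nearest-gene assignment for intergenic
  variants.
* The standard genetic code only; selenocysteine recoding and
  mitochondrial codes are out of scope.
* Consequence calling assumes the annotated CDS is in frame from its
  first base; no frame metadata from genePred `exonFrames` is used.
* Promoter windows are fixed-width and strand-aware but not
  expression- or cell-type-aware.
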