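"""Codon-level consequence calling for CDS-hitting SNVs.

The CDS is assembled 5'→3' on the transcript strand (reverse-complemented
for minus-strand transcripts), translated with the standard genetic code,
and the reference and alternative codons compared. Stop codons are
represented as '*'. The package convention is that the CDS span includes
the stop codon, so stop-loss at the terminal codon is directly callable.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio.Seq import Seq

from .models import (
    CodingConsequence,
    ConsequenceKind,
    CONSEQUENCE_SEVERITY,
    ReannotError,
    STOP_AA,
    TranscriptModel,
    Variant,
)
from .io import Genome

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter, '*' for stop) of one codon, standard code."""
    if len(codon) != 3:
        raise ReannotError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate(table=1))


def assemble_cds(tx: TranscriptModel, genome: Genome) -> tuple[str, dict[int, int]]:
    """Concatenate the CDS on the transcript strand.

    Returns the coding sequence and a bijective map from genomic position
    to 0-based CDS offset (offset 0 = first base of the start codon).
    """
    if not tx.is_coding:
        raise ReannotError(f"transcript {tx.transcript_id!r} has no CDS")
    positions = tx.cds_positions()
    if not positions:
        raise ReannotError(f"transcript {tx.transcript_id!r}: CDS length 0")
    bases = [genome.base(tx.contig, p) for p in positions]
    if tx.strand == "-":
        positions = positions[::-1]
        bases = [b.translate(_COMPLEMENT) for b in bases[::-1]]
    offset_map = {pos: i for i, pos in enumerate(positions)}
    return "".join(bases), offset_map


def call_consequence(
    variant: Variant, tx: TranscriptModel, genome: Genome
) -> CodingConsequence:
    """Consequence of a SNV inside the CDS of one transcript.

    UNKNOWN when the alternative allele is absent or the variant falls in
    a trailing partial codon of a CDS whose length is not a multiple of 3.
    If the declared reference allele disagrees with the genome base, the
    genome defines the reference codon and the call is flagged.
    """
    cds, offset_map = assemble_cds(tx, genome)
    if variant.position not in offset_map:
        raise ReannotError(
            f"variant {variant.id!r} at {variant.contig}:{variant.position} is outside "
            f"the CDS of transcript {tx.transcript_id!r}"
        )
    genome_base = genome.base(variant.contig, variant.position)
    ref_mismatch = variant.ref_allele is not None and variant.ref_allele != genome_base
    if variant.alt_allele is None:
        return CodingConsequence(
            kind=ConsequenceKind.UNKNOWN,
            transcript_id=tx.transcript_id,
            ref_mismatch=ref_mismatch,
        )
    offset = offset_map[variant.position]
    codon_start = (offset // 3) * 3
    if codon_start + 3 > len(cds):
        # trailing partial codon of a CDS not divisible by 3: frame unknown
        return CodingConsequence(
            kind=ConsequenceKind.UNKNOWN,
            transcript_id=tx.transcript_id,
            ref_mismatch=ref_mismatch,
        )
    ref_codon = cds[codon_start : codon_start + 3]
    within = offset - codon_start
    alt_base = (
        variant.alt_allele
        if tx.strand == "+"
        else variant.alt_allele.translate(_COMPLEMENT)
    )
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa != STOP_AA and alt_aa == STOP_AA:
        kind = ConsequenceKind.STOPGAIN
    elif ref_aa == STOP_AA and alt_aa != STOP_AA:
        kind = ConsequenceKind.STOPLOSS
    elif ref_aa == alt_aa:
        # includes the degenerate stop-retained and alt==ref cases
        kind = ConsequenceKind.SYNONYMOUS
    else:
        kind = ConsequenceKind.NONSYNONYMOUS
    return CodingConsequence(
        kind=kind,
        transcript_id=tx.transcript_id,
        codon_index=offset // 3 + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        ref_mismatch=ref_mismatch,
    )


def most_severe(consequences: Sequence[CodingConsequence]) -> CodingConsequence:
    """Most severe consequence of a non-empty collection.

    Severity: STOPGAIN = STOPLOSS > NONSYNONYMOUS > SYNONYMOUS > UNKNOWN;
    ties broken by the lexicographically smallest transcript id.
    """
    if not consequences:
        raise ReannotError("most_severe of an empty consequence list")
    return min(
        consequences,
        key=lambda c: (-CONSEQUENCE_SEVERITY[c.kind], c.transcript_id or ""),
    )
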