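"""Codon-level consequence calling against a frozen genetic-code table."""

import itertools

import pytest

from reannot import (
    ConsequenceKind,
    ExonInterval,
    ReannotError,
    TranscriptModel,
    Variant,
)
from reannot.consequence import (
    assemble_cds,
    call_consequence,
    most_severe,
    reverse_complement,
    translate_codon,
)
from reannot.models import CodingConsequence

K = ConsequenceKind

# Independent oracle: the standard genetic code, frozen here by hand.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def expected_kind(ref_codon: str, alt_codon: str) -> K:
    ra, aa = GENETIC_CODE[ref_codon], GENETIC_CODE[alt_codon]
    if ra != "*" and aa == "*":
        return K.STOPGAIN
    if ra == "*" and aa != "*":
        return K.STOPLOSS
    if ra == aa:
        return K.SYNONYMOUS
    return K.NONSYNONYMOUS


def test_translate_codon_agrees_with_frozen_table():
    for codon, aa in GENETIC_CODE.items():
        assert translate_codon(codon) == aa


class TestAssembleCds:
    def test_plus_strand_simple(self, make_genome):
        genome = make_genome({"c": "TTATGGCCTT"})
        tx = TranscriptModel("t", "g", "c", "+", (ExonInterval(1, 10),), cds_span=(3, 8))
        cds, offsets = assemble_cds(tx, genome)
        assert cds == "ATGGCC"
        assert offsets == {3: 0, 4: 1, 5: 2, 6: 3, 7: 4, 8: 5}

    def test_minus_strand_reverse_complements(self, make_genome):
        genome = make_genome({"c": "TTGGCCATTT"})
        tx = TranscriptModel("t", "g", "c", "-", (ExonInterval(1, 10),), cds_span=(3, 8))
        cds, offsets = assemble_cds(tx, genome)
        assert cds == "ATGGCC"
        # first CDS base (the A of ATG) is the highest genomic coordinate
        assert offsets[8] == 0 and offsets[3] == 5

    def test_two_exon_cds_skips_the_intron(self, make_genome):
        #          123456789012345678
        seq = "AAATGGCAAAAAGCTAAC"  # exon1 3-8, intron 9-12, exon2 13-18
        genome = make_genome({"c": seq})
        tx = TranscriptModel(
            "t", "g", "c", "+",
            (ExonInterval(3, 8), ExonInterval(13, 18)),
            cds_span=(3, 18),
        )
        cds, offsets = assemble_cds(tx, genome)
        # manual walk: bases 3..8 then 13..18
        assert cds == seq[2:8] + seq[12:18] == "ATGGCAGCTAAC"
        assert offsets == {**{p: p - 3 for p in range(3, 9)},
                           **{p: p - 13 + 6 for p in range(13, 19)}}

    def test_noncoding_transcript_is_an_error(self, make_genome):
        genome = make_genome({"c": "ACGTACGT"})
        tx = TranscriptModel("t", "g", "c", "+", (ExonInterval(1, 8),))
        with pytest.raises(ReannotError):
            assemble_cds(tx, genome)


class TestCallConsequence:
    def _tx(self, cds_seq, strand="+", pad="TT"):
        seq = pad + (cds_seq if strand == "+" else reverse_complement(cds_seq)) + pad
        lo, hi = len(pad) + 1, len(pad) + len(cds_seq)
        tx = TranscriptModel("t", "g", "c", strand, (ExonInterval(lo, hi),), cds_span=(lo, hi))
        return seq, tx, lo

    def test_synonymous_third_position(self, make_genome):
        seq, tx, lo = self._tx("ATGGCCTAA")
        genome = make_genome({"c": seq})
        v = Variant("rs1", "c", lo + 5, "C", "A")  # GCC -> GCA, Ala -> Ala
        cons = call_consequence(v, tx, genome)
        assert cons.kind is K.SYNONYMOUS and cons.codon_index == 2
        assert (cons.ref_codon, cons.alt_codon) == ("GCC", "GCA")

    def test_stopgain_and_stoploss(self, make_genome):
        seq, tx, lo = self._tx("ATGTGGTAA")
        genome = make_genome({"c": seq})
        gain = call_consequence(Variant("rs1", "c", lo + 5, "G", "A"), tx, genome)
        assert gain.kind is K.STOPGAIN  # TGG -> TGA
        loss = call_consequence(Variant("rs2", "c", lo + 6, "T", "C"), tx, genome)
        assert loss.kind is K.STOPLOSS and loss.alt_codon == "CAA"  # TAA -> CAA

    def test_absent_alt_allele_is_unknown(self, make_genome):
        seq, tx, lo = self._tx("ATGGCCTAA")
        genome = make_genome({"c": seq})
        cons = call_consequence(Variant("rs1", "c", lo + 4, "C", None), tx, genome)
        assert cons.kind is K.UNKNOWN

    def test_trailing_partial_codon_is_unknown(self, make_genome):
        seq, tx, lo = self._tx("ATGGCCTA")  # length 8, trailing 2-base codon
        genome = make_genome({"c": seq})
        cons = call_consequence(Variant("rs1", "c", lo + 7, "A", "G"), tx, genome)
        assert cons.kind is K.UNKNOWN

    def test_outside_cds_is_an_error(self, make_genome):
        seq, tx, lo = self._tx("ATGGCCTAA")
        genome = make_genome({"c": seq})
        with pytest.raises(ReannotError):
            call_consequence(Variant("rs1", "c", 1, "T", "A"), tx, genome)

    def test_reference_mismatch_flagged_but_called_from_genome(self, make_genome):
        seq, tx, lo = self._tx("ATGGCCTAA")
        genome = make_genome({"c": seq})
        # declared ref T disagrees with genome C at third codon position
        cons = call_consequence(Variant("rs1", "c", lo + 5, "T", "A"), tx, genome)
        assert cons.ref_mismatch and cons.ref_codon == "GCC"
        assert cons.kind is K.SYNONYMOUS

    def test_alt_equal_to_genome_base_degenerates_to_synonymous(self, make_genome):
        seq, tx, lo = self._tx("ATGGCCTAA")
        genome = make_genome({"c": seq})
        cons = call_consequence(Variant("rs1", "c", lo + 5, None, "C"), tx, genome)
        assert cons.ref_codon == cons.alt_codon and cons.kind is K.SYNONYMOUS

    def test_minus_strand_alt_allele_is_complemented(self, make_genome):
        seq, tx, lo = self._tx("ATGTGGTAA", strand="-")
        genome = make_genome({"c": seq})
        # genomic position of the 3rd base of codon TGG (offset 5): offset
        # o maps to position hi - o on the minus strand
        hi = lo + 8
        pos = hi - 5
        # genome shows the complement strand; alt T on the genome is A on
        # the transcript: TGG -> TGA, stop gained
        cons = call_consequence(Variant("rs1", "c", pos, None, "T"), tx, genome)
        assert cons.kind is K.STOPGAIN and cons.alt_codon == "TGA"


class TestExhaustiveEnumeration:
    def test_all_576_codon_substitutions_match_the_frozen_table(self, make_genome):
        """Every (codon, position, alt base) substitution agrees with an
        independent enumeration of the standard genetic code."""
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        sequences = {f"ctg_{c}": f"ATG{c}TAA" for c in codons}
        genome = make_genome(sequences)
        counts = {k: 0 for k in K}
        n_cases = 0
        for codon in codons:
            tx = TranscriptModel(
                f"t_{codon}", "g", f"ctg_{codon}", "+",
                (ExonInterval(1, 9),), cds_span=(1, 9),
            )
            for within in range(3):
                ref = codon[within]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    v = Variant("rs1", f"ctg_{codon}", 4 + within, ref, alt)
                    got = call_consequence(v, tx, genome)
                    alt_codon = codon[:within] + alt + codon[within + 1:]
                    assert got.kind is expected_kind(codon, alt_codon), (codon, within, alt)
                    counts[got.kind] += 1
                    n_cases += 1
        assert n_cases == 576
        # independent per-kind totals from the frozen table
        expected_counts = {k: 0 for k in K}
        for codon in codons:
            for within in range(3):
                for alt in "ACGT":
                    if alt == codon[within]:
                        continue
                    alt_codon = codon[:within] + alt + codon[within + 1:]
                    expected_counts[expected_kind(codon, alt_codon)] += 1
        assert counts == expected_counts
        assert counts[K.UNKNOWN] == 0


class TestMostSevere:
    def _c(self, kind, tx="t1", **kw):
        defaults = dict(
            ref_aa={"SYNONYMOUS": "A", "NONSYNONYMOUS": "A", "STOPGAIN": "A",
                    "STOPLOSS": "*", "UNKNOWN": None}[kind.value],
            alt_aa={"SYNONYMOUS": "A", "NONSYNONYMOUS": "V", "STOPGAIN": "*",
                    "STOPLOSS": "Q", "UNKNOWN": None}[kind.value],
        )
        return CodingConsequence(kind=kind, transcript_id=tx, **{**defaults, **kw})

    def test_nonsynonymous_beats_synonymous(self):
        got = most_severe([self._c(K.SYNONYMOUS), self._c(K.NONSYNONYMOUS, "t2")])
        assert got.kind is K.NONSYNONYMOUS

    def test_stop_changes_beat_everything(self):
        got = most_severe([self._c(K.NONSYNONYMOUS), self._c(K.STOPLOSS, "t0")])
        assert got.kind is K.STOPLOSS

    def test_single_unknown_is_identity(self):
        (c,) = [self._c(K.UNKNOWN)]
        assert most_severe([c]) is c

    def test_ties_broken_by_transcript_id(self):
        a, b = self._c(K.NONSYNONYMOUS, "tB"), self._c(K.NONSYNONYMOUS, "tA")
        assert most_severe([a, b]) is b

    def test_identical_consequence_from_isoforms_sharing_a_cds(self):
        a, b = self._c(K.NONSYNONYMOUS, "tA"), self._c(K.NONSYNONYMOUS, "tB")
        assert most_severe([a, b]).kind is K.NONSYNONYMOUS

    def test_empty_list_is_an_error(self):
        with pytest.raises(ReannotError):
            most_severe([])


def test_strand_symmetry_of_consequences(make_genome):
    """The same CDS placed on either strand yields the same consequence."""
    cds = "ATGTGGGCCTAA"
    pad = "ACGTA"
    plus_seq = pad + cds + pad
    minus_seq = pad + reverse_complement(cds) + pad
    genome = make_genome({"plus": plus_seq, "minus": minus_seq})
    lo, hi = len(pad) + 1, len(pad) + len(cds)
    tx_p = TranscriptModel("tp", "g", "plus", "+", (ExonInterval(lo, hi),), cds_span=(lo, hi))
    tx_m = TranscriptModel("tm", "g", "minus", "-", (ExonInterval(lo, hi),), cds_span=(lo, hi))
    for offset in range(len(cds)):
        for alt_t in "ACGT":
            if alt_t == cds[offset]:
                continue
            vp = Variant("rs1", "plus", lo + offset, None, alt_t)
            vm = Variant("rs1", "minus", hi - offset, None, reverse_complement(alt_t))
            a = call_consequence(vp, tx_p, genome)
            b = call_consequence(vm, tx_m, genome)
            assert (a.kind, a.ref_codon, a.alt_codon) == (b.kind, b.ref_codon, b.alt_codon)
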