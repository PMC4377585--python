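"""Region classification vs an independent per-base brute-force oracle."""

import numpy as np
import pytest

from reannot import (
    AnnotationSet,
    ExonInterval,
    RegionCategory,
    Thresholds,
    TranscriptModel,
    Variant,
    build_index,
    category_counts,
    classify_variant,
    filter_noncoding,
    promoter_interval,
)

C = RegionCategory


# ---------------------------------------------------------------------------
# independent oracle: materialise explicit per-category position sets per
# transcript, then apply the documented precedence.

_PRECEDENCE = [C.CDS, C.SPLICE, C.UTR5, C.UTR3, C.NCRNA_EXONIC, C.INTRONIC, C.PROMOTER]


def brute_force_classify(position, contig, annotation_set, thresholds, use_promoter=True,
                         contig_lengths=None):
    candidates = []
    for tx in annotation_set.transcripts:
        if tx.contig != contig:
            continue
        exonic = set()
        for e in tx.exons:
            exonic.update(range(e.start, e.end + 1))
        cds = set(tx.cds_positions())
        intronic = set(range(tx.start, tx.end + 1)) - exonic
        splice = set()
        for p in intronic:
            boundary_dist = min(
                min(abs(p - e.end) for e in tx.exons if e.end < p),
                min(abs(e.start - p) for e in tx.exons if e.start > p),
            )
            if boundary_dist <= thresholds.splice_window_bp and len(tx.exons) > 1:
                splice.add(p)
        if tx.strand == "+":
            prom = set(range(tx.tss - thresholds.promoter_window_bp, tx.tss))
        else:
            prom = set(range(tx.tss + 1, tx.tss + thresholds.promoter_window_bp + 1))
        prom = {p for p in prom if p >= 1}
        if contig_lengths and contig in contig_lengths:
            prom = {p for p in prom if p <= contig_lengths[contig]}
        if position in cds:
            candidates.append(C.CDS)
        elif position in splice:
            candidates.append(C.SPLICE)
        elif position in exonic and tx.cds_span is not None:
            cs, ce = tx.cds_span
            before = position < cs
            if tx.strand == "+":
                candidates.append(C.UTR5 if before else C.UTR3)
            else:
                candidates.append(C.UTR3 if before else C.UTR5)
        elif position in exonic:
            candidates.append(C.NCRNA_EXONIC)
        elif position in intronic:
            candidates.append(C.INTRONIC)
        elif use_promoter and position in prom:
            candidates.append(C.PROMOTER)
    for cat in _PRECEDENCE:
        if cat in candidates:
            return cat
    return C.INTERGENIC


def _variant(pos, contig="chrS"):
    return Variant(f"rs_{contig}_{pos}", contig, pos, None, None)


# ---------------------------------------------------------------------------


class TestPromoterInterval:
    def test_plus_strand_window_is_directly_upstream(self):
        tx = TranscriptModel("t", "g", "c", "+", (ExonInterval(5000, 5100),))
        assert promoter_interval(tx, 1000) == (4000, 4999)

    def test_minus_strand_window_mirrors(self):
        tx = TranscriptModel("t", "g", "c", "-", (ExonInterval(7000, 8000),))
        assert promoter_interval(tx, 1000) == (8001, 9000)

    def test_clamped_at_contig_start(self):
        tx = TranscriptModel("t", "g", "c", "+", (ExonInterval(500, 600),))
        assert promoter_interval(tx, 1000) == (1, 499)

    def test_clamped_at_contig_end(self):
        tx = TranscriptModel("t", "g", "c", "-", (ExonInterval(500, 900),))
        assert promoter_interval(tx, 1000, {"c": 1200}) == (901, 1200)

    def test_entirely_off_contig_returns_none(self):
        tx = TranscriptModel("t", "g", "c", "+", (ExonInterval(1, 100),))
        assert promoter_interval(tx, 1000) is None


class TestSpliceWindow:
    @pytest.mark.parametrize(
        "offset, expected",
        [(1, C.SPLICE), (2, C.SPLICE), (3, C.INTRONIC)],
    )
    def test_intron_offset_against_two_bp_window(self, simple_set, offset, expected):
        # intron spans 51..90; offset measured from the upstream exon end (50)
        call = classify_variant(_variant(50 + offset, "chr1"), simple_set)
        assert call.category is expected

    def test_exonic_base_near_boundary_stays_exonic(self, simple_set):
        call = classify_variant(_variant(50, "chr1"), simple_set)  # last exon base
        assert call.category is C.CDS


class TestClassifyVariant:
    def test_cds_hit(self, simple_set):
        assert classify_variant(_variant(100, "chr1"), simple_set).category is C.CDS

    def test_utrs_are_strand_aware(self, simple_set):
        assert classify_variant(_variant(25, "chr1"), simple_set).category is C.UTR5
        assert classify_variant(_variant(120, "chr1"), simple_set).category is C.UTR3

    def test_absent_contig_gives_intergenic(self, simple_set):
        assert classify_variant(_variant(100, "chrZ"), simple_set).category is C.INTERGENIC

    def test_promoter_toggle(self, simple_set):
        v = _variant(10, "chr1")  # upstream of TSS=21
        assert classify_variant(v, simple_set).category is C.PROMOTER
        assert classify_variant(v, simple_set, use_promoter=False).category is C.INTERGENIC

    def test_intragenic_beats_promoter_of_a_neighbor(self):
        aset = AnnotationSet(
            "s",
            (
                TranscriptModel("t1", "gA", "c", "+",
                                (ExonInterval(100, 200), ExonInterval(300, 400))),
                TranscriptModel("t2", "gB", "c", "+", (ExonInterval(450, 600),)),
            ),
        )
        # position 250: intron of gA and promoter window of gB
        call = classify_variant(_variant(250, "c"), aset)
        assert call.category is C.INTRONIC and call.gene_ids == ("gA",)

    def test_gene_ids_sorted_across_overlapping_genes(self):
        aset = AnnotationSet(
            "s",
            (
                TranscriptModel("tz", "zgene", "c", "+", (ExonInterval(100, 300),)),
                TranscriptModel("ta", "agene", "c", "-", (ExonInterval(150, 350),)),
            ),
        )
        call = classify_variant(_variant(200, "c"), aset)
        assert call.category is C.NCRNA_EXONIC and call.gene_ids == ("agene", "zgene")


class TestIndex:
    def test_empty_set_returns_nothing(self):
        idx = build_index(AnnotationSet("s", ()))
        assert idx.query("chr1", 100) == []

    def test_query_equals_linear_scan_on_random_transcripts(self):
        rng = np.random.default_rng(0)
        txs = []
        for i in range(200):
            start = int(rng.integers(1_100, 90_000))
            n_ex = int(rng.integers(1, 4))
            exons, cur = [], start
            for _ in range(n_ex):
                length = int(rng.integers(20, 120))
                exons.append(ExonInterval(cur, cur + length - 1))
                cur += length + int(rng.integers(30, 150))
            txs.append(
                TranscriptModel(f"t{i}", f"g{i}", "chrS",
                                "+" if i % 2 else "-", tuple(exons))
            )
        aset = AnnotationSet("s", tuple(txs))
        t = Thresholds()
        idx = build_index(aset, t)

        def scan(pos):
            hits = []
            for tx in txs:
                lo, hi = tx.start, tx.end
                prom = promoter_interval(tx, t.promoter_window_bp)
                if prom:
                    lo, hi = min(lo, prom[0]), max(hi, prom[1])
                if lo <= pos <= hi:
                    hits.append(tx.transcript_id)
            return sorted(hits)

        for pos in rng.integers(1, 95_000, size=400):
            pos = int(pos)
            assert [t_.transcript_id for t_ in idx.query("chrS", pos)] == scan(pos)

    def test_exon_start_coordinate_is_inclusive(self, simple_set, simple_transcript):
        idx = build_index(simple_set)
        assert simple_transcript in idx.query("chr1", 21)


class TestOracleEquivalence:
    @pytest.mark.parametrize("use_promoter", [True, False])
    def test_matches_bruteforce_on_generated_annotation_sets(self, fixture_run, use_promoter):
        """Engine equals the per-base oracle at hundreds of random positions."""
        from reannot.io import parse_gene_models, read_genome

        base = fixture_run.out_dir
        genome = read_genome(base / "genome.fa")
        lengths = genome.contig_lengths
        aset = parse_gene_models(base / "baseline.gtf", "gtf", "baseline", "baseline")
        alt = parse_gene_models(base / "altA.gtf", "gtf", "altA")
        t = Thresholds()
        rng = np.random.default_rng(5)
        positions = [int(p) for p in rng.integers(1, lengths["chrS"], size=300)]
        positions += [pv.variant.position for pv in fixture_run.ground_truth.variants.values()]
        for s in (aset, alt):
            idx = build_index(s, t, lengths)
            for pos in positions:
                got = classify_variant(
                    _variant(pos), s, t, index=idx, use_promoter=use_promoter
                ).category
                want = brute_force_classify(pos, "chrS", s, t, use_promoter, lengths)
                assert got is want, (s.name, pos, got, want)

    def test_order_invariance(self, fixture_run):
        from reannot.io import parse_gene_models

        aset = parse_gene_models(fixture_run.out_dir / "altA.gtf", "gtf", "altA")
        shuffled = AnnotationSet("altA", tuple(reversed(aset.transcripts)), "alternative")
        rng = np.random.default_rng(3)
        for pos in rng.integers(1, 60_000, size=150):
            v = _variant(int(pos))
            a = classify_variant(v, aset)
            b = classify_variant(v, shuffled)
            assert (a.category, a.gene_ids) == (b.category, b.gene_ids)

    def test_strand_symmetry_under_genome_mirroring(self, fixture_run):
        """Mirroring all coordinates and flipping strands preserves categories."""
        from reannot.io import parse_gene_models

        aset = parse_gene_models(fixture_run.out_dir / "altA.gtf", "gtf", "altA")
        L = 200_000  # mirror: position p -> L + 1 - p

        def mirror_tx(tx):
            exons = tuple(
                ExonInterval(L + 1 - e.end, L + 1 - e.start) for e in reversed(tx.exons)
            )
            span = None
            if tx.cds_span:
                span = (L + 1 - tx.cds_span[1], L + 1 - tx.cds_span[0])
            return TranscriptModel(tx.transcript_id, tx.gene_id, tx.contig,
                                   "-" if tx.strand == "+" else "+", exons, span)

        mirrored = AnnotationSet("m", tuple(mirror_tx(t) for t in aset.transcripts))
        rng = np.random.default_rng(4)
        for pos in rng.integers(1, 60_000, size=200):
            pos = int(pos)
            a = classify_variant(_variant(pos), aset).category
            b = classify_variant(_variant(L + 1 - pos), mirrored).category
            assert a is b, (pos, a, b)

    def test_promoter_window_monotonicity(self, fixture_run):
        """Enlarging the promoter window only converts INTERGENIC to PROMOTER."""
        from reannot.io import parse_gene_models

        aset = parse_gene_models(fixture_run.out_dir / "altA.gtf", "gtf", "altA")
        rng = np.random.default_rng(6)
        small, big = Thresholds(), Thresholds(promoter_window_bp=2500)
        for pos in rng.integers(1, 60_000, size=250):
            v = _variant(int(pos))
            a = classify_variant(v, aset, small).category
            b = classify_variant(v, aset, big).category
            if a is not b:
                assert (a, b) == (C.INTERGENIC, C.PROMOTER)


class TestFilterNoncoding:
    def test_partition_is_exact_and_matches_categories(self, fixture_run):
        from reannot.io import parse_gene_models, read_variants

        base = fixture_run.out_dir
        variants = read_variants(base / "variants.tsv", "tsv")
        baseline = parse_gene_models(base / "baseline.gtf", "gtf", "baseline", "baseline")
        kept, removed = filter_noncoding(variants, baseline)
        assert len(kept) + len(removed) == len(variants)
        truth = fixture_run.ground_truth.variants
        assert {v.id for v in removed} == {i for i, pv in truth.items() if pv.removed}

    def test_baseline_exonic_and_splice_removed_intergenic_kept(self, simple_set):
        cds = _variant(100, "chr1")
        splice = _variant(52, "chr1")  # 2 bp into the intron
        away = _variant(5000, "chr1")
        kept, removed = filter_noncoding([cds, splice, away], simple_set)
        assert [v.id for v in removed] == [cds.id, splice.id]
        assert [v.id for v in kept] == [away.id]

    def test_requires_baseline_role(self, simple_transcript):
        alt = AnnotationSet("a", (simple_transcript,), "alternative")
        with pytest.raises(ValueError):
            filter_noncoding([], alt)


class TestCategoryCounts:
    def test_empty_input_gives_empty_table(self):
        assert category_counts([]).empty

    def test_rows_sum_to_number_of_variants_and_match_plan(self, fixture_run):
        from reannot.pipeline import run_from_manifest

        res = run_from_manifest(fixture_run.out_dir / "manifest.json")
        calls = [c for calls in res.alt_calls.values() for c in calls.values()]
        table = category_counts(calls)
        n = len(res.noncoding)
        assert (table.sum(axis=1) == n).all()
        truth = fixture_run.ground_truth.variants
        for set_name in res.alt_calls:
            for cat in RegionCategory:
                planted = sum(
                    1
                    for pv in truth.values()
                    if not pv.removed and pv.per_set_category[set_name] is cat
                )
                assert table.loc[set_name, cat.value] == planted
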