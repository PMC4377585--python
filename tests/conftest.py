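"""Shared fixtures: tiny hand-built genomes/annotations and one generated
synthetic input directory reused across test modules."""

from __future__ import annotations

import pytest

from reannot import (
    AnnotationSet,
    ExonInterval,
    FixtureSpec,
    Thresholds,
    TranscriptModel,
    generate_fixture,
)
from reannot.io import read_genome, write_fasta


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One generated synthetic input directory (seed 1) with ground truth."""
    out = tmp_path_factory.mktemp("fixture") / "fx"
    return generate_fixture(FixtureSpec(seed=1), out)


@pytest.fixture()
def make_genome(tmp_path):
    """Write named contigs to FASTA and return a Genome accessor."""

    def _make(sequences: dict[str, str]):
        path = tmp_path / "genome.fa"
        write_fasta(sequences, path)
        return read_genome(path)

    return _make


@pytest.fixture()
def simple_transcript():
    """Plus-strand 2-exon coding transcript on a 200 bp contig.

    Exons 21-50 and 91-130; CDS 31-110 (spanning the intron); UTRs on
    both sides.
    """
    return TranscriptModel(
        transcript_id="tx1",
        gene_id="gene1",
        contig="chr1",
        strand="+",
        exons=(ExonInterval(21, 50), ExonInterval(91, 130)),
        cds_span=(31, 110),
    )


@pytest.fixture()
def simple_set(simple_transcript):
    return AnnotationSet(name="baseline", transcripts=(simple_transcript,), role="baseline")


@pytest.fixture()
def default_thresholds():
    return Thresholds()
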