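"""Readers and writers for the external formats the tool touches.

Supported inputs: FASTA genomes (via pyfaidx), GTF and genePred gene
models, sites-only VCF or tabular variant lists, BED3+ regulatory tracks
and TSV expression tables. All coordinate conversion between external
0-based half-open conventions and the internal 1-based inclusive
convention happens here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from .models import (
    AnnotationSet,
    CodingConsequence,
    ConsequenceKind,
    ExonInterval,
    ExpressionRecord,
    ReannotError,
    ReannotationDelta,
    RegionCall,
    RegionCategory,
    RegulatoryFeatureClass,
    RegulatoryProfile,
    TrackFeature,
    TranscriptCall,
    TranscriptModel,
    Variant,
    validate_variant,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# ---------------------------------------------------------------------------
# gene models


def _transcripts_from_gtf(path: PathLike) -> Iterable[TranscriptModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, contig, strand)
    skipped: set[str] = set()
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("exon", "CDS"):
            if feat.featuretype not in skipped:
                skipped.add(feat.featuretype)
                logger.warning("skipping unknown feature type %r in %s", feat.featuretype, path)
            continue
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ReannotError(
                f"{path}: {feat.featuretype} record lacks required attribute {exc}"
            ) from None
        meta[tx_id] = (gene_id, feat.seqid, feat.strand)
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tx_id, []).append((feat.start, feat.end))
    for tx_id, (gene_id, contig, strand) in meta.items():
        ex = sorted(exons.get(tx_id, []))
        if not ex:
            # CDS-only transcript: treat CDS records as its exons
            ex = sorted(cds[tx_id])
        span = None
        if tx_id in cds:
            blocks = cds[tx_id]
            span = (min(s for s, _ in blocks), max(e for _, e in blocks))
        try:
            yield TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                exons=tuple(ExonInterval(s, e) for s, e in ex),
                cds_span=span,
            )
        except ReannotError as exc:
            raise ReannotError(f"{path}: {exc}") from None


def _transcripts_from_genepred(path: PathLike) -> Iterable[TranscriptModel]:
    # genePred: name chrom strand txStart txEnd cdsStart cdsEnd exonCount
    # exonStarts exonEnds [score name2 cdsStartStat cdsEndStat exonFrames]
    # coordinates are 0-based half-open.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (10, 15):
                raise ReannotError(
                    f"{path}:{lineno}: genePred rows need 10 or 15 columns, got {len(fields)}"
                )
            name, chrom, strand = fields[0], fields[1], fields[2]
            cds_start0, cds_end0 = int(fields[5]), int(fields[6])
            starts = [int(x) for x in fields[8].rstrip(",").split(",")]
            ends = [int(x) for x in fields[9].rstrip(",").split(",")]
            gene = fields[11] if len(fields) == 15 and fields[11] else name
            span = None if cds_start0 >= cds_end0 else (cds_start0 + 1, cds_end0)
            try:
                yield TranscriptModel(
                    transcript_id=name,
                    gene_id=gene,
                    contig=chrom,
                    strand=strand,
                    exons=tuple(ExonInterval(s + 1, e) for s, e in zip(starts, ends)),
                    cds_span=span,
                )
            except ReannotError as exc:
                raise ReannotError(f"{path}:{lineno}: {exc}") from None


def parse_gene_models(
    path: PathLike,
    dialect: str,
    set_name: str,
    role: str = "alternative",
    alias_map: Optional[Mapping[str, str]] = None,
) -> AnnotationSet:
    """Read a GTF or genePred file into an :class:`AnnotationSet`.

    Minus-strand transcripts keep genomic-ascending exon order; transcripts
    without CDS records are noncoding. ``alias_map`` optionally renames
    contigs (e.g. ``{"1": "chr1"}``); no renaming happens otherwise.
    """
    if dialect == "gtf":
        transcripts = list(_transcripts_from_gtf(path))
    elif dialect == "genepred":
        transcripts = list(_transcripts_from_genepred(path))
    else:
        raise ReannotError(f"unknown gene-model dialect {dialect!r} (use 'gtf' or 'genepred')")
    if alias_map:
        transcripts = [
            TranscriptModel(
                transcript_id=tx.transcript_id,
                gene_id=tx.gene_id,
                contig=alias_map.get(tx.contig, tx.contig),
                strand=tx.strand,
                exons=tx.exons,
                cds_span=tx.cds_span,
            )
            for tx in transcripts
        ]
    return AnnotationSet(name=set_name, transcripts=tuple(transcripts), role=role)


def write_gtf(annotation_set: AnnotationSet, path: PathLike) -> None:
    """Write an annotation set as minimal Ensembl-style GTF (exon + CDS rows)."""
    with open(path, "w") as fh:
        fh.write(f"#!annotation-set {annotation_set.name} role={annotation_set.role}\n")
        for tx in annotation_set.transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for exon in tx.exons:
                fh.write(
                    f"{tx.contig}\treannot\texon\t{exon.start}\t{exon.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds_span is not None:
                cs, ce = tx.cds_span
                for exon in tx.exons:
                    lo, hi = max(exon.start, cs), min(exon.end, ce)
                    if lo <= hi:
                        fh.write(
                            f"{tx.contig}\treannot\tCDS\t{lo}\t{hi}\t.\t{tx.strand}\t.\t{attrs}\n"
                        )


def write_genepred(annotation_set: AnnotationSet, path: PathLike) -> None:
    """Write an annotation set as 15-column genePred (0-based half-open)."""
    with open(path, "w") as fh:
        for tx in annotation_set.transcripts:
            if tx.cds_span is None:
                cds_start0 = cds_end0 = tx.exons[0].start - 1
            else:
                cds_start0, cds_end0 = tx.cds_span[0] - 1, tx.cds_span[1]
            starts = ",".join(str(e.start - 1) for e in tx.exons) + ","
            ends = ",".join(str(e.end) for e in tx.exons) + ","
            fh.write(
                "\t".join(
                    [
                        tx.transcript_id,
                        tx.contig,
                        tx.strand,
                        str(tx.exons[0].start - 1),
                        str(tx.exons[-1].end),
                        str(cds_start0),
                        str(cds_end0),
                        str(len(tx.exons)),
                        starts,
                        ends,
                        "0",
                        tx.gene_id,
                        "none",
                        "none",
                        ",".join("-1" for _ in tx.exons) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# variants

_TSV_SYNONYMS = {
    "id": {"id", "rsid", "rs_id", "snp", "snp_id", "name"},
    "contig": {"contig", "chrom", "chr", "chromosome"},
    "position": {"position", "pos", "chr_pos", "bp"},
    "ref": {"ref", "ref_allele", "reference"},
    "alt": {"alt", "alt_allele", "risk_allele", "alternative"},
    "trait": {"trait", "disease", "phenotype", "disease_trait"},
}


def _auto_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for key, names in _TSV_SYNONYMS.items():
        for cand in names:
            if cand in lower:
                mapping[key] = lower[cand]
                break
    missing = {"id", "contig", "position"} - set(mapping)
    if missing:
        raise ReannotError(
            f"variant TSV: cannot locate columns for {sorted(missing)}; "
            f"supply a column_map"
        )
    return mapping


def _dedup(variants: Iterable[Variant]) -> list[Variant]:
    seen: set[str] = set()
    out: list[Variant] = []
    dups = 0
    for v in variants:
        if v.id in seen:
            dups += 1
            continue
        seen.add(v.id)
        out.append(v)
    if dups:
        logger.info("dropped %d duplicate variant record(s) (first occurrence kept)", dups)
    return out


def _clean_allele(raw) -> Optional[str]:
    if raw is None:
        return None
    s = str(raw).strip().upper()
    if s in ("", ".", "-", "?", "N", "NA", "NAN", "NONE"):
        return None
    return s


def read_variants(
    path: PathLike,
    dialect: str = "tsv",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[Variant]:
    """Read SNVs from a sites-only VCF or a tabular catalog file.

    Rows without a usable identifier and rows that fail validation (indels,
    position < 1) are skipped with a warning. Duplicated identifiers keep
    the first occurrence; the number dropped is logged.
    """
    variants: list[Variant] = []
    skipped = 0
    if dialect == "vcf":
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf.fetch() if vcf.index is not None else vcf:
                vid = rec.id
                if vid is None or vid == ".":
                    skipped += 1
                    continue
                alt = rec.alts[0] if rec.alts else None
                try:
                    variants.append(
                        validate_variant(
                            Variant(
                                id=vid,
                                contig=rec.contig,
                                position=rec.pos,
                                ref_allele=_clean_allele(rec.ref),
                                alt_allele=_clean_allele(alt),
                            )
                        )
                    )
                except ReannotError as exc:
                    skipped += 1
                    logger.warning("skipping VCF record %s: %s", vid, exc)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = dict(column_map) if column_map else _auto_columns(df.columns)
        for _, row in df.iterrows():
            vid = row.get(cols["id"])
            if vid is None or pd.isna(vid) or not str(vid).strip():
                skipped += 1
                logger.warning("skipping variant row without identifier")
                continue
            try:
                variants.append(
                    validate_variant(
                        Variant(
                            id=str(vid).strip(),
                            contig=str(row[cols["contig"]]).strip(),
                            position=int(row[cols["position"]]),
                            ref_allele=_clean_allele(row.get(cols["ref"])) if "ref" in cols else None,
                            alt_allele=_clean_allele(row.get(cols["alt"])) if "alt" in cols else None,
                            trait=(
                                str(row[cols["trait"]]).strip()
                                if "trait" in cols and pd.notna(row.get(cols["trait"]))
                                else None
                            ),
                        )
                    )
                )
            except (ReannotError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping unparsable variant row (%s)", exc)
    else:
        raise ReannotError(f"unknown variant dialect {dialect!r} (use 'vcf' or 'tsv')")
    if skipped:
        logger.info("skipped %d unusable variant row(s)", skipped)
    return _dedup(variants)


def write_variants_tsv(variants: Sequence[Variant], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcontig\tposition\tref\talt\ttrait\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.id,
                        v.contig,
                        str(v.position),
                        v.ref_allele or "",
                        v.alt_allele or "",
                        v.trait or "",
                    ]
                )
                + "\n"
            )


def write_variants_vcf(
    variants: Sequence[Variant], path: PathLike, contig_lengths: Optional[Mapping[str, int]] = None
) -> None:
    """Write a minimal sites-only VCF (missing alleles become 'N'/'.')."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=reannot\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (x.contig, x.position, x.id)):
            fh.write(
                f"{v.contig}\t{v.position}\t{v.id}\t{v.ref_allele or 'N'}\t"
                f"{v.alt_allele or '.'}\t.\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# regulatory tracks


def read_tracks(
    tracks: Sequence[tuple[PathLike, RegulatoryFeatureClass]],
) -> list[TrackFeature]:
    """Read BED3+ files, one feature class per file.

    BED intervals stay 0-based half-open in memory; rows with start >= end
    are rejected with a warning.
    """
    out: list[TrackFeature] = []
    for path, feature_class in tracks:
        name = Path(path).name
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    logger.warning("%s:%d: fewer than 3 BED columns, row rejected", name, lineno)
                    continue
                try:
                    start, end = int(fields[1]), int(fields[2])
                    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                    out.append(
                        TrackFeature(
                            contig=fields[0],
                            start=start,
                            end=end,
                            feature_class=feature_class,
                            source_track=name,
                            score=score,
                        )
                    )
                except (ValueError, ReannotError) as exc:
                    logger.warning("%s:%d: row rejected (%s)", name, lineno, exc)
    return out


def write_track_bed(features: Sequence[TrackFeature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda x: (x.contig, x.start, x.end)):
            score = "." if f.score is None else str(f.score)
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.feature_class.value}\t{score}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: PathLike) -> list[ExpressionRecord]:
    """Read a gene x tissue expression table (TSV).

    Requires columns gene_id, tissue, estimate, posterior_sd. Rows with a
    negative estimate or SD are rejected with a warning; a duplicated
    (gene, tissue) pair is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "tissue", "estimate", "posterior_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ReannotError(f"{path}: expression table lacks columns {sorted(missing)}")
    records: list[ExpressionRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (str(row["gene_id"]), str(row["tissue"]))
        if key in seen:
            raise ReannotError(f"{path}: duplicated (gene, tissue) pair {key}")
        seen.add(key)
        try:
            records.append(
                ExpressionRecord(
                    gene_id=key[0],
                    tissue=key[1],
                    estimate=float(row["estimate"]),
                    posterior_sd=float(row["posterior_sd"]),
                )
            )
        except ReannotError as exc:
            logger.warning("%s: row rejected (%s)", path, exc)
    return records


def write_expression_tsv(records: Sequence[ExpressionRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttissue\testimate\tposterior_sd\n")
        for r in sorted(records, key=lambda x: (x.gene_id, x.tissue)):
            fh.write(f"{r.gene_id}\t{r.tissue}\t{r.estimate:.6g}\t{r.posterior_sd:.6g}\n")


# ---------------------------------------------------------------------------
# genome access


class Genome:
    """Uppercased random access over an (indexed) FASTA file."""

    def __init__(self, path: PathLike):
        self._fasta = Fasta(str(path), sequence_always_upper=True, as_raw=True)
        self.path = str(path)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.records.items()}

    def _check(self, contig: str, start: int, end: int) -> None:
        if contig not in self._fasta.records:
            raise ReannotError(f"contig {contig!r} not in genome {self.path}")
        length = len(self._fasta.records[contig])
        if start < 1 or end > length or start > end:
            raise ReannotError(
                f"query {contig}:{start}-{end} outside contig bounds 1-{length}"
            )

    def base(self, contig: str, position: int) -> str:
        """Single base at a 1-based position."""
        self._check(contig, position, position)
        return str(self._fasta[contig][position - 1 : position])

    def slice(self, contig: str, start: int, end: int) -> str:
        """Bases over a 1-based inclusive interval."""
        self._check(contig, start, end)
        return str(self._fasta[contig][start - 1 : end])

    def close(self) -> None:
        self._fasta.close()


def read_genome(path: PathLike) -> Genome:
    return Genome(path)


def write_fasta(sequences: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# results

RESULT_SCHEMA_VERSION = 1


def _record_to_row(obj) -> dict:
    if isinstance(obj, RegionCall):
        return {
            "record": "region_call",
            "variant_id": obj.variant_id,
            "set_name": obj.set_name,
            "category": obj.category.value,
            "gene_ids": ",".join(obj.gene_ids),
        }
    if isinstance(obj, ReannotationDelta):
        return {
            "record": "reannotation_delta",
            "variant_id": obj.variant_id,
            "set_name": "",
            "baseline_category": obj.baseline_category.value,
            "per_set_category": ";".join(
                f"{k}={v.value}" for k, v in sorted(obj.per_set_category.items())
            ),
            "is_reannotated": str(obj.is_reannotated),
            "coding_support": str(obj.coding_support),
            "reannotating_sets": ",".join(sorted(obj.reannotating_sets)),
        }
    if isinstance(obj, RegulatoryProfile):
        return {
            "record": "regulatory_profile",
            "variant_id": obj.variant_id,
            "set_name": "",
            "classes": ",".join(sorted(c.value for c in obj.classes)),
            "n_classes": str(obj.n_classes),
        }
    raise ReannotError(f"no writer for result objects of type {type(obj).__name__}")


def write_results(
    records: Sequence, path: PathLike, fmt: str = "tsv", parameters: Optional[Mapping] = None
) -> None:
    """Write computed results deterministically (sorted by variant, then set).

    TSV output documents its columns in '#' header comment lines; JSON
    output is ``{"schema_version": ..., "parameters": ..., "records": [...]}``.
    """
    rows = sorted(
        (_record_to_row(r) for r in records),
        key=lambda r: (r["variant_id"], r.get("set_name", "")),
    )
    columns: list[str] = []
    for row in rows:
        for key in row:
            if key not in columns:
                columns.append(key)
    if fmt == "tsv":
        with open(path, "w") as fh:
            if parameters:
                fh.write(f"# parameters: {json.dumps(parameters, sort_keys=True)}\n")
            fh.write("# columns: " + ", ".join(columns) + "\n")
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(row.get(c, "") for c in columns) + "\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(
                {
                    "schema_version": RESULT_SCHEMA_VERSION,
                    "parameters": dict(parameters) if parameters else {},
                    "records": rows,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
    else:
        raise ReannotError(f"unknown result format {fmt!r} (use 'tsv' or 'json')")


def read_results(path: PathLike, fmt: str = "tsv") -> list[dict]:
    """Read rows previously written by :func:`write_results`."""
    if fmt == "tsv":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
        if not lines:
            return []
        header = lines[0].split("\t")
        return [
            {k: v for k, v in zip(header, ln.split("\t"))}
            for ln in lines[1:]
            if ln
        ]
    if fmt == "json":
        with open(path) as fh:
            return json.load(fh)["records"]
    raise ReannotError(f"unknown result format {fmt!r}")
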