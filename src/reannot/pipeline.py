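"""End-to-end orchestration: filter, classify, integrate, profile, summarise.

The full run mirrors the method's stages:

1. classify every variant against the baseline set and drop those in
   exonic or splice-window regions of baseline protein-coding genes;
2. classify the retained ("baseline-noncoding") variants against every
   alternative set;
3. build re-annotation deltas and call coding consequences for variants
   any alternative set places in a CDS;
4. overlap the retained variants with regulatory-feature tracks;
5. apply the expressed-gene criterion to the genes harboring
   re-annotated variants.

Baseline classification runs without the PROMOTER category (a promoter
window is only credited during re-annotation against the alternative
sets); pass ``baseline_use_promoter=True`` to remove the asymmetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import classify as _classify
from . import expression as _expression
from . import integrate as _integrate
from . import io as rio
from . import regulatory as _regulatory
from .consequence import call_consequence
from .models import (
    AnnotationSet,
    CodingConsequence,
    ConsequenceKind,
    ExpressionRecord,
    RegionCall,
    RegionCategory,
    ReannotationDelta,
    RegulatoryProfile,
    Thresholds,
    TrackFeature,
    Variant,
)

__all__ = ["PipelineResult", "run_pipeline", "load_inputs", "run_from_manifest"]


@dataclass
class PipelineResult:
    noncoding: list[Variant]
    removed: list[Variant]
    baseline_calls: dict[str, RegionCall]
    alt_calls: dict[str, dict[str, RegionCall]]
    deltas: list[ReannotationDelta]
    consequences: dict[str, list[CodingConsequence]]
    profiles: dict[str, RegulatoryProfile]
    expressed_genes: set[str]
    tissue_specific: set[str]
    expressed_summary: dict[str, tuple[int, int]]
    summary: dict = field(default_factory=dict)


def run_pipeline(
    variants: Sequence[Variant],
    baseline: AnnotationSet,
    alternatives: Sequence[AnnotationSet],
    genome: Optional[rio.Genome] = None,
    tracks: Sequence[TrackFeature] = (),
    expression_records: Sequence[ExpressionRecord] = (),
    thresholds: Thresholds = Thresholds(),
    baseline_use_promoter: bool = False,
) -> PipelineResult:
    contig_lengths = genome.contig_lengths if genome is not None else None
    noncoding, removed = _classify.filter_noncoding(
        variants, baseline, thresholds, contig_lengths
    )
    baseline_calls = _classify.classify_all(
        noncoding, baseline, thresholds,
        use_promoter=baseline_use_promoter, contig_lengths=contig_lengths,
    )
    alt_calls = {
        aset.name: _classify.classify_all(
            noncoding, aset, thresholds, contig_lengths=contig_lengths
        )
        for aset in alternatives
    }
    deltas = _integrate.reannotate(noncoding, baseline_calls, alt_calls)

    consequences: dict[str, list[CodingConsequence]] = {}
    if genome is not None:
        tx_by_set = {
            aset.name: {tx.transcript_id: tx for tx in aset.transcripts}
            for aset in alternatives
        }
        for delta in deltas:
            if delta.coding_support < 1:
                continue
            cons: list[CodingConsequence] = []
            variant = next(v for v in noncoding if v.id == delta.variant_id)
            for set_name, calls in alt_calls.items():
                call = calls[delta.variant_id]
                if call.category is not RegionCategory.CDS:
                    continue
                for tc in call.transcript_calls:
                    if tc.category is not RegionCategory.CDS:
                        continue
                    tx = tx_by_set[set_name][tc.transcript_id]
                    cons.append(call_consequence(variant, tx, genome))
            consequences[delta.variant_id] = cons

    profiles = _regulatory.overlap_features(noncoding, tracks)
    _, expressed_genes = _expression.flag_expressed(expression_records, thresholds)
    tissue_specific = _expression.tissue_specific_genes(expression_records, thresholds)
    expressed_summary = _expression.expressed_gas_gene_summary(
        deltas, expressed_genes, genes_in_table={r.gene_id for r in expression_records}
    )

    breakdown = (
        _integrate.consequence_breakdown(deltas, consequences)
        if genome is not None
        else {k: 0 for k in ConsequenceKind}
    )
    counts = _classify.category_counts(
        [c for calls in alt_calls.values() for c in calls.values()]
    )
    hist = _regulatory.feature_count_distribution(profiles)
    summary = {
        "n_variants": len(variants),
        "n_noncoding": len(noncoding),
        "n_removed": len(removed),
        "n_reannotated_union": len(_integrate.reannotated_union(deltas)),
        "per_set_reannotated": {
            s: len(ids) for s, ids in _integrate.per_set_reannotated(deltas).items()
        },
        "consequence_breakdown": {k.value: v for k, v in breakdown.items()},
        "category_counts": {
            s: {c: int(counts.loc[s, c]) for c in counts.columns}
            for s in counts.index
        },
        "regulatory_histogram": {str(k): v for k, v in hist.items()},
        "regulatory_coverage_fraction": _regulatory.coverage_fraction(profiles),
        "n_expressed_genes": len(expressed_genes),
        "n_tissue_specific_genes": len(tissue_specific),
        "expressed_summary": {
            s: {"genes": g, "variants": v} for s, (g, v) in expressed_summary.items()
        },
        "thresholds": {
            "splice_window_bp": thresholds.splice_window_bp,
            "promoter_window_bp": thresholds.promoter_window_bp,
            "expression_sd_max": thresholds.expression_sd_max,
        },
    }
    return PipelineResult(
        noncoding=noncoding,
        removed=removed,
        baseline_calls=baseline_calls,
        alt_calls=alt_calls,
        deltas=deltas,
        consequences=consequences,
        profiles=profiles,
        expressed_genes=expressed_genes,
        tissue_specific=tissue_specific,
        expressed_summary=expressed_summary,
        summary=summary,
    )


def load_inputs(manifest_path) -> dict:
    """Load every input named by a fixture/run manifest (JSON)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    sets = {}
    for entry in manifest["sets"]:
        sets[entry["name"]] = rio.parse_gene_models(
            base / entry["path"], entry["dialect"], entry["name"], entry["role"]
        )
    from .models import RegulatoryFeatureClass

    tracks = rio.read_tracks(
        [
            (base / path, RegulatoryFeatureClass(cls))
            for cls, path in sorted(manifest.get("tracks", {}).items())
        ]
    )
    thresholds = Thresholds(**manifest.get("thresholds", {}))
    return {
        "variants": rio.read_variants(base / manifest["variants_tsv"], "tsv"),
        "genome": rio.read_genome(base / manifest["genome"]),
        "baseline": next(s for s in sets.values() if s.role == "baseline"),
        "alternatives": [s for s in sets.values() if s.role == "alternative"],
        "tracks": tracks,
        "expression": rio.read_expression(base / manifest["expression"]),
        "thresholds": thresholds,
    }


def run_from_manifest(
    manifest_path, out_dir=None, thresholds: Optional[Thresholds] = None
) -> PipelineResult:
    """Run the full pipeline on a manifest directory; optionally write results."""
    inputs = load_inputs(manifest_path)
    result = run_pipeline(
        variants=inputs["variants"],
        baseline=inputs["baseline"],
        alternatives=inputs["alternatives"],
        genome=inputs["genome"],
        tracks=inputs["tracks"],
        expression_records=inputs["expression"],
        thresholds=thresholds or inputs["thresholds"],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        params = result.summary["thresholds"]
        all_calls = list(result.baseline_calls.values()) + [
            c for calls in result.alt_calls.values() for c in calls.values()
        ]
        rio.write_results(all_calls, out_dir / "region_calls.tsv", "tsv", params)
        rio.write_results(result.deltas, out_dir / "deltas.tsv", "tsv", params)
        rio.write_results(
            list(result.profiles.values()), out_dir / "regulatory_profiles.tsv", "tsv", params
        )
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return result
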