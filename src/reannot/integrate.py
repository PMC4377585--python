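"""Cross-database integration: re-annotation deltas and consensus support.

This is the central step of the method: variants the baseline annotation
calls intronic or intergenic are compared against each alternative
annotation set, and a variant is re-annotated when at least one
alternative set places it in a promoter or intragenic region (an
alternative intronic call counts only when the baseline was intergenic).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .models import (
    CodingConsequence,
    ConsequenceKind,
    ReannotError,
    ReannotationDelta,
    RegionCall,
    RegionCategory,
    Variant,
    reannotates,
)
from .consequence import most_severe


def reannotate(
    variants: Sequence[Variant],
    baseline_calls: Mapping[str, RegionCall],
    alt_calls: Mapping[str, Mapping[str, RegionCall]],
) -> list[ReannotationDelta]:
    """Build one delta per variant from baseline and per-set calls.

    ``alt_calls`` maps alternative set name -> (variant id -> RegionCall).
    Every variant must have a call in the baseline and in every
    alternative set; a missing call is an error naming variant and set.
    Deltas are returned sorted by variant id.
    """
    deltas: list[ReannotationDelta] = []
    for v in sorted(variants, key=lambda x: x.id):
        if v.id not in baseline_calls:
            raise ReannotError(f"variant {v.id!r} missing from baseline calls")
        base = baseline_calls[v.id]
        per_set: dict[str, RegionCategory] = {}
        per_genes: dict[str, tuple[str, ...]] = {}
        reann_sets: set[str] = set()
        support = 0
        for set_name, calls in alt_calls.items():
            if v.id not in calls:
                raise ReannotError(
                    f"variant {v.id!r} missing from calls of annotation set {set_name!r}"
                )
            call = calls[v.id]
            per_set[set_name] = call.category
            per_genes[set_name] = call.gene_ids
            if reannotates(base.category, call.category):
                reann_sets.add(set_name)
            if call.category is RegionCategory.CDS:
                support += 1
        deltas.append(
            ReannotationDelta(
                variant_id=v.id,
                baseline_category=base.category,
                per_set_category=per_set,
                per_set_genes=per_genes,
                is_reannotated=bool(reann_sets),
                coding_support=support,
                reannotating_sets=frozenset(reann_sets),
            )
        )
    return deltas


def reannotated_union(deltas: Sequence[ReannotationDelta]) -> set[str]:
    """Variant ids re-annotated by at least one alternative set.

    Set semantics: a variant re-annotated by several sets (or to several
    categories) counts once.
    """
    return {d.variant_id for d in deltas if d.is_reannotated}


def per_set_reannotated(deltas: Sequence[ReannotationDelta]) -> dict[str, set[str]]:
    """Variant ids re-annotated by each alternative set individually."""
    out: dict[str, set[str]] = {}
    for d in deltas:
        for set_name in d.per_set_category:
            out.setdefault(set_name, set())
        for set_name in d.reannotating_sets:
            out[set_name].add(d.variant_id)
    return out


def coding_support(delta: ReannotationDelta, alt_calls: Mapping[str, Mapping[str, RegionCall]]) -> int:
    """Number of alternative sets whose top-level category is CDS."""
    n = 0
    for set_name, calls in alt_calls.items():
        call = calls.get(delta.variant_id)
        if call is None:
            raise ReannotError(
                f"variant {delta.variant_id!r} missing from calls of set {set_name!r}"
            )
        if call.category is RegionCategory.CDS:
            n += 1
    return n


def consequence_breakdown(
    deltas: Sequence[ReannotationDelta],
    consequences: Mapping[str, Sequence[CodingConsequence]],
) -> dict[ConsequenceKind, int]:
    """Per-kind counts of coding-reclassified variants.

    Counts variants with ``coding_support >= 1`` by the most severe
    consequence across all transcripts of all supporting sets; the counts
    sum to the number of coding-reclassified variants. ``consequences``
    maps variant id -> consequences collected from CDS transcript calls.
    """
    counts = {kind: 0 for kind in ConsequenceKind}
    for d in deltas:
        if d.coding_support < 1:
            continue
        cons = consequences.get(d.variant_id)
        if not cons:
            raise ReannotError(
                f"variant {d.variant_id!r} has coding support but no consequences supplied"
            )
        counts[most_severe(cons).kind] += 1
    return counts
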