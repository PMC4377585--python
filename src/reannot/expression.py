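"""Expressed-gene filtering and summaries for re-annotated variants.

Expression estimates (point estimate plus posterior standard deviation,
per gene per tissue) are consumed from an upstream quantification
pipeline; a gene is called expressed in a tissue when its posterior SD is
strictly below the configured maximum (default 1.5), separating genuinely
quantified genes from noise-level estimates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .models import ExpressionRecord, ReannotationDelta, Thresholds

logger = logging.getLogger(__name__)


def flag_expressed(
    records: Sequence[ExpressionRecord], thresholds: Thresholds = Thresholds()
) -> tuple[set[tuple[str, str]], set[str]]:
    """Expressed (gene, tissue) pairs and genes expressed in >= 1 tissue."""
    pairs = {
        (r.gene_id, r.tissue) for r in records if r.is_expressed(thresholds)
    }
    genes = {g for g, _ in pairs}
    return pairs, genes


def tissue_specific_genes(
    records: Sequence[ExpressionRecord], thresholds: Thresholds = Thresholds()
) -> set[str]:
    """Genes expressed in exactly one tissue."""
    per_gene: dict[str, set[str]] = {}
    for r in records:
        if r.is_expressed(thresholds):
            per_gene.setdefault(r.gene_id, set()).add(r.tissue)
    return {g for g, tissues in per_gene.items() if len(tissues) == 1}


def gas_harboring_genes(
    deltas: Sequence[ReannotationDelta],
) -> dict[str, dict[str, set[str]]]:
    """Per alternative set: gene id -> ids of re-annotated variants it harbors.

    Only sets that actually re-annotated the variant contribute; the genes
    are those the set's region call attributed the category to.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for d in deltas:
        for set_name in d.per_set_category:
            out.setdefault(set_name, {})
        for set_name in d.reannotating_sets:
            for gene in d.per_set_genes.get(set_name, ()):
                out[set_name].setdefault(gene, set()).add(d.variant_id)
    return out


def expressed_gas_gene_summary(
    deltas: Sequence[ReannotationDelta],
    expressed_genes: set[str],
    genes_in_table: set[str] | None = None,
) -> dict[str, tuple[int, int]]:
    """Per set: (number of expressed variant-harboring genes, variants harbored).

    A gene counts when it harbors at least one re-annotated variant in
    that set and is expressed in at least one tissue; the variant count is
    the number of distinct re-annotated variants in those expressed genes.
    Genes absent from the expression table (when ``genes_in_table`` is
    given) are treated as not expressed and logged.
    """
    summary: dict[str, tuple[int, int]] = {}
    for set_name, genes in gas_harboring_genes(deltas).items():
        if genes_in_table is not None:
            missing = [g for g in genes if g not in genes_in_table]
            if missing:
                logger.info(
                    "set %s: %d variant-harboring gene(s) absent from the expression "
                    "table, treated as not expressed",
                    set_name,
                    len(missing),
                )
        expressed = {g: vs for g, vs in genes.items() if g in expressed_genes}
        variants: set[str] = set()
        for vs in expressed.values():
            variants |= vs
        summary[set_name] = (len(expressed), len(variants))
    return summary
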