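"""Variant-to-gene assignment and binary gene (burden) matrices.

Bacterial genomes are dense with overlapping genes, so a variant falling
inside two genes belongs to both: the assignment step duplicates such
variant rows across every gene whose interval contains the position.
Gene matrices are the logical OR of the contributing variant rows —
presence/absence of any qualifying variant in the gene — optionally
stratified by SnpEff predicted functional impact, where the impact is a
property of the (variant, gene) pair: the same SNP can be HIGH impact in
one gene of an overlapping pair and LOW in the other.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alleles import IMPACT_CATEGORIES
from .binarize import BinaryVariantMatrix
from .io import GeneRecord

logger = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = ["row_key", "gene"]


def assign_to_genes(bvm: BinaryVariantMatrix, genes: Sequence[GeneRecord],
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Assign each variant row to every gene whose interval contains it.

    Membership is 1-based inclusive containment of the variant position
    on the matching contig; strand is ignored.  Returns the (row_key,
    gene) assignment table — one row per overlapping gene, so a variant
    inside two overlapping genes appears twice — and the list of
    intergenic row keys (excluded from gene matrices, logged).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id)
    pairs, intergenic = [], []
    for row in bvm.meta.itertuples(index=False):
        hits = trees.get(row.chrom, IntervalTree())[row.pos]
        if not hits:
            intergenic.append(row.row_key)
            continue
        for iv in sorted(hits, key=lambda iv: iv.data):
            pairs.append((row.row_key, iv.data))
    if intergenic:
        logger.info("%d variant rows are intergenic and excluded from gene "
                    "matrices", len(intergenic))
    return pd.DataFrame(pairs, columns=ASSIGNMENT_COLUMNS), intergenic


def collapse_to_genes(bvm: BinaryVariantMatrix,
                      assignment: pd.DataFrame) -> pd.DataFrame:
    """Binary gene matrix: OR of all variant rows assigned to each gene.

    Genes with no assigned rows are absent.  Row order is sorted by gene
    id for determinism.
    """
    if assignment.empty:
        return pd.DataFrame(columns=bvm.samples, dtype=np.int8,
                            index=pd.Index([], name="gene"))
    joined = bvm.data.loc[assignment["row_key"]].copy()
    joined.index = pd.Index(assignment["gene"].values, name="gene")
    out = joined.groupby(level=0).max().sort_index().astype(np.int8)
    return out


def impact_matrix_suite(bvm: BinaryVariantMatrix, assignment: pd.DataFrame,
                        impacts: pd.DataFrame,
                        custom: Iterable[str] | None = None,
                        ) -> dict[str, pd.DataFrame]:
    """Gene matrices: ALL plus one per impact category, plus optional CUSTOM.

    The impact filter applies per (variant row, gene) pair via the
    (chrom, pos, alt, gene) impact table, so a variant shared by
    overlapping genes can contribute to different categories in each.
    With an empty impact table only ALL is produced.  ``custom`` is a
    subset of the four SnpEff categories whose contributions are unioned.
    """
    suite = {"ALL": collapse_to_genes(bvm, assignment)}
    if impacts is None or impacts.empty:
        if custom:
            raise ValueError("custom impact subset requested but the input "
                             "carries no impact annotations")
        return suite
    if custom is not None:
        custom = sorted(set(custom))
        bad = [c for c in custom if c not in IMPACT_CATEGORIES]
        if bad:
            raise ValueError(
                f"unknown impact categories {bad}; expected a subset of "
                f"{list(IMPACT_CATEGORIES)}")

    meta = bvm.meta.set_index("row_key")
    ann = assignment.copy()
    ann["chrom"] = meta.loc[ann["row_key"], "chrom"].values
    ann["pos"] = meta.loc[ann["row_key"], "pos"].values
    ann["alt"] = meta.loc[ann["row_key"], "alt"].values
    ann = ann.merge(impacts, how="left",
                    on=["chrom", "pos", "alt", "gene"])

    for category in IMPACT_CATEGORIES:
        sub = ann[ann["impact"] == category][ASSIGNMENT_COLUMNS]
        suite[category] = collapse_to_genes(bvm, sub)
    if custom is not None:
        sub = ann[ann["impact"].isin(custom)][ASSIGNMENT_COLUMNS]
        suite["CUSTOM:" + ",".join(custom)] = collapse_to_genes(bvm, sub)
    return suite
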