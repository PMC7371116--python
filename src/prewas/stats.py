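"""Dataset characterisation statistics.

Summary quantities that describe why the pre-processing choices matter
for a given dataset: how common multiallelic sites are, how diverse the
samples are (mean pairwise SNP distance), whether the alternate alleles
of triallelic sites agree in predicted functional impact, and how often
a variant shared by overlapping genes has discordant impacts between
them.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .alleles import AlleleMatrix

logger = logging.getLogger(__name__)


def multiallelic_fraction(matrix: AlleleMatrix) -> tuple[int, int, float]:
    """(# multiallelic sites, # variant sites, fraction).

    A site is multiallelic when more than two distinct non-"N" alleles
    are observed; variant sites are those with at least two.  The
    fraction is 0 when there are no variant sites.
    """
    n_variant = 0
    n_multi = 0
    for i in range(matrix.n_sites):
        k = len(matrix.distinct_alleles(i))
        if k >= 2:
            n_variant += 1
        if k > 2:
            n_multi += 1
    frac = n_multi / n_variant if n_variant else 0.0
    return n_multi, n_variant, frac


def mean_pairwise_snp_distance(matrix: AlleleMatrix) -> float:
    """Mean over unordered sample pairs of the count of differing sites.

    Sites where either member of the pair is "N" are ignored for that
    pair (complete-pair deletion).
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("pairwise distance requires >=2 samples")
    cells = matrix.values()
    valid = cells != "N"
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        both = valid[:, i] & valid[:, j]
        total += int((cells[both, i] != cells[both, j]).sum())
        pairs += 1
    return total / pairs


def triallelic_impact_concordance(impacts: pd.DataFrame,
                                  matrix: AlleleMatrix) -> dict:
    """Impact (mis)match tallies for allele pairs at multiallelic sites.

    For every site with more than two distinct non-"N" alleles, each
    unordered pair of alternate alleles with a known impact in the same
    gene is scored as a match (same category) or mismatch.
    """
    matched = mismatched = 0
    if impacts is not None and not impacts.empty:
        by_site = impacts.groupby(["chrom", "pos"])
        for i in range(matrix.n_sites):
            if len(matrix.distinct_alleles(i)) <= 2:
                continue
            chrom = matrix.sites["chrom"].iat[i]
            pos = int(matrix.sites["pos"].iat[i])
            try:
                sub = by_site.get_group((chrom, pos))
            except KeyError:
                continue
            observed = matrix.distinct_alleles(i)
            for gene, gsub in sub.groupby("gene"):
                gsub = gsub[gsub["alt"].isin(observed)]
                imp = dict(zip(gsub["alt"], gsub["impact"]))
                for a, b in itertools.combinations(sorted(imp), 2):
                    if imp[a] == imp[b]:
                        matched += 1
                    else:
                        mismatched += 1
    total = matched + mismatched
    return {
        "matched": matched,
        "mismatched": mismatched,
        "mismatch_fraction": mismatched / total if total else None,
    }


def overlap_impact_discordance(impacts: pd.DataFrame,
                               assignment: pd.DataFrame,
                               meta: pd.DataFrame) -> dict:
    """Fraction of multi-gene variants with discordant impacts across genes.

    Over variant rows assigned to two or more genes with a known impact in
    at least two of them, the fraction where the impact categories are not
    all identical.  With no such rows the fraction is reported as
    not-applicable (None).
    """
    evaluated = discordant = 0
    if (impacts is not None and not impacts.empty and assignment is not None
            and not assignment.empty):
        counts = assignment["row_key"].value_counts()
        multi = counts[counts >= 2].index
        m = meta.set_index("row_key")
        ann = assignment[assignment["row_key"].isin(multi)].copy()
        if not ann.empty:
            ann["chrom"] = m.loc[ann["row_key"], "chrom"].values
            ann["pos"] = m.loc[ann["row_key"], "pos"].values
            ann["alt"] = m.loc[ann["row_key"], "alt"].values
            ann = ann.merge(impacts, how="inner",
                            on=["chrom", "pos", "alt", "gene"])
            for key, sub in ann.groupby("row_key"):
                if len(sub) < 2:
                    continue
                evaluated += 1
                if sub["impact"].nunique() > 1:
                    discordant += 1
    return {
        "evaluated": evaluated,
        "discordant": discordant,
        "discordant_fraction": discordant / evaluated if evaluated else None,
        "status": "ok" if evaluated else "not_applicable",
    }


def dataset_summary(matrix: AlleleMatrix,
                    impacts: pd.DataFrame | None = None,
                    assignment: pd.DataFrame | None = None,
                    meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """One-row summary table of the dataset-characterisation statistics."""
    n_multi, n_variant, frac = multiallelic_fraction(matrix)
    row = {
        "samples": len(matrix.samples),
        "variant_sites": n_variant,
        "multiallelic_sites": n_multi,
        "multiallelic_fraction": frac,
        "mean_snp_distance": (mean_pairwise_snp_distance(matrix)
                              if len(matrix.samples) >= 2 else np.nan),
    }
    if assignment is not None and not assignment.empty:
        counts = assignment["row_key"].value_counts()
        multi_rows = counts[counts >= 2].index
        if meta is not None:
            m = meta.set_index("row_key")
            row["snps_in_overlapping_genes"] = (
                m.loc[m.index.isin(multi_rows), "pos"].nunique())
        else:
            row["snps_in_overlapping_genes"] = len(multi_rows)
    if impacts is not None:
        tri = triallelic_impact_concordance(impacts, matrix)
        row["triallelic_impact_mismatch_fraction"] = tri["mismatch_fraction"]
        if assignment is not None and meta is not None:
            ov = overlap_impact_discordance(impacts, assignment, meta)
            row["overlap_impact_discordant_fraction"] = ov["discordant_fraction"]
    return pd.DataFrame([row])
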