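"""Single-line allele matrix construction and SnpEff impact parsing.

The merged VCF is converted into a sites x samples matrix of allele
strings with one row per genomic position and missing data rendered as
the literal fifth state "N".  When the VCF carries SnpEff ``ANN``
annotations they are parsed into a tidy (site, alt, gene, impact) table
used later to stratify gene matrices by predicted functional impact.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, VariantTable

logger = logging.getLogger(__name__)

IMPACT_CATEGORIES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: columns of the tidy impact table
IMPACT_COLUMNS = ["chrom", "pos", "alt", "gene", "impact"]


def site_key(chrom: str, pos: int, single_contig: bool) -> str:
    """Row key for a genomic position: "<pos>", chrom-prefixed if multi-contig."""
    return str(pos) if single_contig else f"{chrom}|{pos}"


@dataclasses.dataclass
class AlleleMatrix:
    """Sites x samples allele strings; missing data coded as "N".

    ``sites`` carries per-row metadata (chrom, pos, ref_genome allele,
    site key) in genomic order; ``cells`` is the matching object array of
    allele strings.
    """

    samples: list[str]
    sites: pd.DataFrame          # columns: key, chrom, pos, ref_genome
    cells: np.ndarray            # shape (n_sites, n_samples), dtype object

    @property
    def n_sites(self) -> int:
        return self.cells.shape[0]

    @property
    def single_contig(self) -> bool:
        return self.sites["chrom"].nunique() <= 1

    def site_keys(self) -> list[str]:
        return list(self.sites["key"])

    def values(self) -> np.ndarray:
        return self.cells

    def row(self, i: int) -> list[str]:
        return list(self.cells[i])

    def distinct_alleles(self, i: int) -> set[str]:
        """Distinct non-"N" alleles observed at site i."""
        return {a for a in self.cells[i] if a != "N"}

    def invariant_mask(self) -> np.ndarray:
        """True for sites with fewer than two distinct non-"N" alleles.

        Such sites stay in the matrix but are dropped at binarization.
        """
        return np.array([len(self.distinct_alleles(i)) < 2
                         for i in range(self.n_sites)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.site_keys(),
                            columns=self.samples)


def build_allele_matrix(table: VariantTable,
                        samples: Sequence[str] | None = None) -> AlleleMatrix:
    """Convert a validated :class:`~prewas.io.VariantTable` to an AlleleMatrix.

    Cell (s, k) is the allele string of sample k's call at site s (indels
    included verbatim); MISSING becomes "N".  Sites are ordered by (chrom,
    pos); sample order defaults to the VCF header order.
    """
    if samples is None:
        samples = list(table.samples)
    col = {s: j for j, s in enumerate(table.samples)}
    unknown = [s for s in samples if s not in col]
    if unknown:
        raise ValueError("samples not in VCF: " + ", ".join(unknown))
    records = sorted(table.records, key=lambda r: (r.chrom, r.pos))
    single = len({r.chrom for r in records}) <= 1
    cells = np.empty((len(records), len(samples)), dtype=object)
    meta = []
    for i, rec in enumerate(records):
        meta.append((site_key(rec.chrom, rec.pos, single), rec.chrom,
                     rec.pos, rec.ref))
        for j, s in enumerate(samples):
            cells[i, j] = rec.allele(rec.calls[col[s]])
    sites = pd.DataFrame(meta, columns=["key", "chrom", "pos", "ref_genome"])
    return AlleleMatrix(samples=list(samples), sites=sites, cells=cells)


def parse_snpeff(table: VariantTable) -> pd.DataFrame:
    """Parse SnpEff ``ANN`` entries into a tidy impact table.

    ANN entries follow "Allele|Annotation|Impact|Gene_Name|Gene_ID|...";
    one row is produced per (site, alt, gene) combination.  Entries for
    alleles absent from the site's ALT list are dropped with a warning,
    as are entries with fewer than four pipe-separated fields or an
    unrecognised impact category.  Exact duplicates are deduplicated.
    An empty table (no ANN anywhere) disables impact-stratified outputs.
    """
    rows = []
    for rec in table.records:
        alts = set(rec.alts)
        for entry in rec.ann:
            fields = entry.split("|")
            if len(fields) < 4:
                warnings.warn(
                    f"ANN entry with <4 fields at {rec.chrom}:{rec.pos} "
                    f"skipped: {entry!r}")
                continue
            allele, impact = fields[0], fields[2]
            gene = fields[4] if len(fields) > 4 and fields[4] else fields[3]
            if allele not in alts:
                warnings.warn(
                    f"ANN allele {allele!r} at {rec.chrom}:{rec.pos} is not "
                    "in the site's ALT list; entry dropped")
                continue
            if impact not in IMPACT_CATEGORIES:
                warnings.warn(
                    f"unknown impact {impact!r} at {rec.chrom}:{rec.pos}; "
                    "entry dropped")
                continue
            if not gene:
                warnings.warn(
                    f"ANN entry without gene at {rec.chrom}:{rec.pos} dropped")
                continue
            rows.append((rec.chrom, rec.pos, allele, gene, impact))
    df = pd.DataFrame(rows, columns=IMPACT_COLUMNS)
    return df.drop_duplicates(ignore_index=True)
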