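"""Binary variant matrix with multi-line representation of multiallelic sites.

Each retained site contributes one 0/1 row per distinct non-reference,
non-"N" allele observed there: a 1 marks samples carrying exactly that
alternate allele, a 0 marks the reference allele, any other alternate
allele, or missing data.  A biallelic site therefore yields one row and a
triallelic site two — the multi-line representation that keeps minor
alleles of multiallelic sites visible to downstream association testing.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleMatrix
from .referencing import ReferenceAssignment

logger = logging.getLogger(__name__)

REASON_ALL_ZERO = "all_zero_row"
REASON_ALL_ONE = "all_one_row"

META_COLUMNS = ["row_key", "site", "chrom", "pos", "alt", "reference_allele",
                "method"]


@dataclasses.dataclass
class BinaryVariantMatrix:
    """0/1 variant presence matrix, rows keyed "<pos>.<alt>".

    ``meta`` has one row per matrix row (site key, alt allele, chosen
    reference, method); ``drop_log`` records every removed site or row
    with its reason.
    """

    data: pd.DataFrame          # rows x samples, int8
    meta: pd.DataFrame          # META_COLUMNS
    drop_log: pd.DataFrame      # columns: site, reason

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)


def split_site(row: Sequence[str], ref: str,
               genome_ref: str | None = None) -> list[tuple[str, np.ndarray]]:
    """Split one site into per-alternate-allele binary rows.

    Returns (alt allele, 0/1 vector) pairs, alts in alphabetical order.
    ``ref`` must belong to the site's allele universe (observed alleles
    plus the genome reference) and cannot be "N".
    """
    if ref == "N":
        raise ValueError("reference allele cannot be the missing state 'N'")
    universe = set(row)
    if genome_ref is not None:
        universe.add(genome_ref)
    if ref not in universe:
        raise ValueError(
            f"reference allele {ref!r} is not in the site's allele universe")
    alts = sorted(a for a in set(row) if a not in (ref, "N"))
    arr = np.asarray(row, dtype=object)
    return [(a, (arr == a).astype(np.int8)) for a in alts]


def binarize_all(matrix: AlleleMatrix,
                 refs: Sequence[ReferenceAssignment]) -> BinaryVariantMatrix:
    """Binary variant matrix over all retained sites, in genomic order.

    ``refs`` must cover every site of ``matrix``.  Removed sites go to the
    drop log with their removal reason; rows that come out all-zero or
    all-one (possible in genome mode when the genome reference allele is
    unobserved) are dropped with their own reason.
    """
    by_key = {a.site_key: a for a in refs}
    missing = [k for k in matrix.site_keys() if k not in by_key]
    if missing:
        raise ValueError("reference assignments missing for sites: "
                         + ", ".join(missing[:5]))
    n_samples = len(matrix.samples)
    rows, keys, meta, dropped = [], [], [], []
    for i, key in enumerate(matrix.site_keys()):
        a = by_key[key]
        if a.removed:
            dropped.append((key, a.removal_reason))
            continue
        genome_ref = matrix.sites["ref_genome"].iat[i]
        for alt, vec in split_site(matrix.row(i), a.reference_allele,
                                   genome_ref=genome_ref):
            total = int(vec.sum())
            if total == 0:
                dropped.append((f"{key}.{alt}", REASON_ALL_ZERO))
                continue
            if total == n_samples:
                dropped.append((f"{key}.{alt}", REASON_ALL_ONE))
                continue
            keys.append(f"{key}.{alt}")
            rows.append(vec)
            meta.append((f"{key}.{alt}", key, matrix.sites["chrom"].iat[i],
                         int(matrix.sites["pos"].iat[i]), alt,
                         a.reference_allele, a.method))
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_samples), dtype=np.int8),
        index=pd.Index(keys, name="variant"), columns=matrix.samples,
        dtype=np.int8)
    return BinaryVariantMatrix(
        data=data,
        meta=pd.DataFrame(meta, columns=META_COLUMNS),
        drop_log=pd.DataFrame(dropped, columns=["site", "reason"]),
    )
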