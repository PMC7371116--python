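"""Per-site reference allele selection and site-removal rules.

The binary encoding needs, for every site, the allele coded 0.  Three
methods are supported:

* ``genome`` — the reference-genome allele from variant calling,
* ``major`` — the most common allele in the dataset, missing data ("N")
  counting as a competing fifth allele,
* ``ancestral`` — the maximum-likelihood root allele from ancestral
  reconstruction on the sample phylogeny (the recommended method: every
  1 in the resulting matrix is then a derived mutation).

Removal rules: a site whose major allele is "N" (major mode) or whose ML
root state is "N" (ancestral mode) is removed; invariant sites are
removed with reason "invariant".  In ancestral mode a site whose root
confidence falls below the threshold (default 0.875) falls back to the
major allele and is flagged, not removed.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleMatrix
from . import phylo as _phylo

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.875

REASON_ROOT_MISSING = "root_is_missing"
REASON_MAJOR_MISSING = "major_is_missing"
REASON_INVARIANT = "invariant"
NOTE_FALLBACK = "low_confidence_fallback_used"

MODES = ("ancestral", "major", "genome")


@dataclasses.dataclass
class ReferenceAssignment:
    site_key: str
    method: str                      # ancestral | major | genome
    reference_allele: str | None     # None iff removed
    confidence: float                # root confidence or major-allele frequency
    removed: bool = False
    removal_reason: str | None = None
    note: str | None = None          # e.g. low_confidence_fallback_used


def major_allele(row: Sequence[str]) -> tuple[str | None, float]:
    """Modal allele of one site, "N" competing as a fifth allele.

    Returns (allele, frequency); allele is None when the mode is "N",
    which removes the site.  Ties among non-"N" alleles break
    alphabetically; "N" wins only when strictly modal.
    """
    counts = Counter(row)
    top = max(counts.values())
    winners = sorted(a for a, c in counts.items() if c == top)
    non_n = [a for a in winners if a != "N"]
    if non_n:
        return non_n[0], top / len(row)
    return None, top / len(row)


def ancestral_allele(dist: _phylo.RootDistribution, row: Sequence[str],
                     threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                     ) -> tuple[str | None, float, str | None, str | None]:
    """Reference allele from the ML root state of one site.

    Returns (allele, confidence, removal_reason, note).  A root state of
    "N" removes the site; a confidence below ``threshold`` falls back to
    the major allele of the row (flagged), which can itself remove the
    site when the major allele is "N".
    """
    if dist.ml_state == "N":
        return None, dist.confidence, REASON_ROOT_MISSING, None
    if dist.confidence < threshold:
        allele, _ = major_allele(row)
        if allele is None:
            return None, dist.confidence, REASON_MAJOR_MISSING, NOTE_FALLBACK
        return allele, dist.confidence, None, NOTE_FALLBACK
    return dist.ml_state, dist.confidence, None, None


def _assign_site(mode: str, matrix: AlleleMatrix, i: int, invariant: bool,
                 recon: _phylo.ReconstructionResult | None,
                 threshold: float) -> ReferenceAssignment:
    key = matrix.sites["key"].iat[i]
    row = matrix.row(i)
    if invariant:
        return ReferenceAssignment(site_key=key, method=mode,
                                   reference_allele=None, confidence=np.nan,
                                   removed=True,
                                   removal_reason=REASON_INVARIANT)
    if mode == "genome":
        return ReferenceAssignment(
            site_key=key, method=mode,
            reference_allele=matrix.sites["ref_genome"].iat[i],
            confidence=1.0)
    if mode == "major":
        allele, freq = major_allele(row)
        if allele is None:
            return ReferenceAssignment(site_key=key, method=mode,
                                       reference_allele=None, confidence=freq,
                                       removed=True,
                                       removal_reason=REASON_MAJOR_MISSING)
        return ReferenceAssignment(site_key=key, method=mode,
                                   reference_allele=allele, confidence=freq)
    # ancestral
    dist = recon.root_distribution(key)
    allele, conf, reason, note = ancestral_allele(dist, row, threshold)
    return ReferenceAssignment(site_key=key, method=mode,
                               reference_allele=allele, confidence=conf,
                               removed=reason is not None,
                               removal_reason=reason, note=note)


def select_references(matrix: AlleleMatrix, mode: str,
                      tree: _phylo.Phylogeny | None = None,
                      threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                      reconstruction: _phylo.ReconstructionResult | None = None,
                      ) -> tuple[list[ReferenceAssignment], dict]:
    """Choose a reference allele for every site and tabulate method mismatches.

    ``mode`` selects the assignments returned; the mismatch report
    compares all methods that are computable (ancestral requires a tree,
    built by neighbour joining when absent and ``mode='ancestral'``).
    Fractions are over retained sites whose root confidence is at least
    ``threshold`` (mirroring how method disagreement is usually reported),
    alongside the fraction of low-confidence sites.
    """
    if mode not in MODES:
        raise ValueError(f"unknown referencing mode {mode!r}")
    need_recon = mode == "ancestral"
    if need_recon and reconstruction is None:
        if tree is None:
            if len(matrix.samples) < 3:
                raise _phylo.PhyloError(
                    "ancestral mode with <3 samples requires a tree")
            tree = _phylo.build_nj_tree(matrix)
            tree = _phylo.root_tree(tree)
        reconstruction = _phylo.reconstruct_root(matrix, tree)
    elif reconstruction is None and tree is not None:
        reconstruction = _phylo.reconstruct_root(matrix, tree)

    invariant = matrix.invariant_mask()
    assignments = [
        _assign_site(mode, matrix, i, bool(invariant[i]), reconstruction,
                     threshold)
        for i in range(matrix.n_sites)
    ]

    report = _mismatch_report(matrix, invariant, reconstruction, threshold)
    return assignments, report


def _mismatch_report(matrix: AlleleMatrix, invariant: np.ndarray,
                     recon: _phylo.ReconstructionResult | None,
                     threshold: float) -> dict:
    """Pairwise disagreement fractions between referencing methods.

    Computed over variant sites retained by every compared method; when a
    reconstruction is available, additionally restricted to sites with
    root confidence >= threshold, and the low-confidence fraction is
    reported separately.
    """
    keys = matrix.site_keys()
    n_total = matrix.n_sites
    rows = {}
    low_conf = 0
    n_variant = 0
    for i in range(n_total):
        if invariant[i]:
            continue
        n_variant += 1
        row = matrix.row(i)
        genome = matrix.sites["ref_genome"].iat[i]
        major, _ = major_allele(row)
        anc = conf = None
        if recon is not None:
            dist = recon.root_distribution(keys[i])
            conf = dist.confidence
            if conf < threshold:
                low_conf += 1
                continue
            anc = dist.ml_state if dist.ml_state != "N" else None
        if major is None or (recon is not None and anc is None):
            continue
        rows[keys[i]] = (genome, major, anc)

    if n_variant == 0:
        return {"status": "0 sites retained", "n_sites": int(n_total),
                "n_variant_sites": 0, "n_compared": 0}
    report: dict = {
        "status": "ok",
        "n_sites": int(n_total),
        "n_variant_sites": int(n_variant),
        "n_compared": len(rows),
        "low_confidence_fraction": (low_conf / n_variant
                                    if recon is not None else None),
    }
    if rows:
        trip = list(rows.values())
        n = len(trip)
        report["genome_vs_major"] = sum(g != m for g, m, _ in trip) / n
        if recon is not None:
            report["genome_vs_ancestral"] = sum(g != a for g, _, a in trip) / n
            report["major_vs_ancestral"] = sum(m != a for _, m, a in trip) / n
    return report


def assignments_frame(assignments: Sequence[ReferenceAssignment]) -> pd.DataFrame:
    """Reference log as a tidy table (one row per site)."""
    return pd.DataFrame(
        [(a.site_key, a.method, a.reference_allele or "",
          a.confidence, a.removed, a.removal_reason or "", a.note or "")
         for a in assignments],
        columns=["site", "method", "reference_allele", "confidence",
                 "removed", "removal_reason", "note"],
    )
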