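"""End-to-end orchestration: VCF in, binary matrices and logs out.

`run_prewas` composes the individual modules with no hidden state — its
output equals calling the modules by hand — and writes a reproducible
output bundle: the binary variant matrix, the reference and drop logs,
the gene matrix suite (when a GFF is supplied), a dataset summary and a
run manifest.  Two runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from . import phylo as _phylo
from .alleles import AlleleMatrix, build_allele_matrix, parse_snpeff
from .binarize import BinaryVariantMatrix, binarize_all
from .genes import assign_to_genes, impact_matrix_suite
from .io import read_gff, read_multivcf, read_tree, write_matrix
from .referencing import (DEFAULT_CONFIDENCE_THRESHOLD, assignments_frame,
                          select_references)
from .stats import dataset_summary

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunResult:
    """In-memory view of one pre-processing run."""

    allele_matrix: AlleleMatrix
    variant_matrix: BinaryVariantMatrix
    reference_log: pd.DataFrame
    mismatch_report: dict
    gene_matrices: dict[str, pd.DataFrame] | None
    summary: pd.DataFrame
    output_dir: Path
    reconstruction: "_phylo.ReconstructionResult | None" = None


def run_prewas(vcf: str | Path, output_dir: str | Path,
               tree: str | Path | None = None,
               outgroup: str | None = None,
               gff: str | Path | None = None,
               mode: str = "ancestral",
               threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
               impact_subset: Iterable[str] | None = None,
               seed: int = 0) -> RunResult:
    """Run the full pre-processing workflow and write the output bundle.

    ``mode`` picks the reference-allele method (default ``ancestral``
    with major-allele fallback at low root confidence); ancestral mode
    without a tree builds a neighbour-joining tree from the SNP data.
    The GFF is required only for the gene matrices.  ``seed`` is recorded
    in the manifest; the pipeline itself is deterministic.
    """
    if outgroup is not None and tree is None:
        raise ValueError("an outgroup requires a tree to root")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    table = read_multivcf(vcf)
    matrix = build_allele_matrix(table)
    impacts = parse_snpeff(table)

    phy = recon = None
    if mode == "ancestral":
        if tree is not None:
            phy = read_tree(tree, samples=table.samples)
            phy = _phylo.prepare_tree(phy, table.samples, outgroup=outgroup)
        else:
            logger.info("no tree supplied: building a neighbour-joining tree")
            phy = _phylo.root_tree(_phylo.build_nj_tree(matrix))
        recon = _phylo.reconstruct_root(matrix, phy)

    refs, report = select_references(matrix, mode, tree=phy,
                                     threshold=threshold,
                                     reconstruction=recon)
    bvm = binarize_all(matrix, refs)
    if bvm.n_rows == 0:
        warnings.warn("all sites were removed; the variant matrix is empty")

    gene_matrices = None
    assignment = None
    if gff is not None:
        genes = read_gff(gff)
        assignment, intergenic = assign_to_genes(bvm, genes)
        gene_matrices = impact_matrix_suite(
            bvm, assignment, impacts,
            custom=list(impact_subset) if impact_subset else None)

    summary = dataset_summary(matrix, impacts=impacts, assignment=assignment,
                              meta=bvm.meta)

    # ---- write bundle ----
    write_matrix(bvm.data, output_dir / "prewas_variant_matrix.tsv")
    ref_log = assignments_frame(refs)
    ref_log.to_csv(output_dir / "prewas_reference_log.tsv", sep="\t",
                   index=False, lineterminator="\n")
    bvm.drop_log.to_csv(output_dir / "prewas_drop_log.tsv", sep="\t",
                        index=False, lineterminator="\n")
    summary.to_csv(output_dir / "prewas_summary.tsv", sep="\t", index=False,
                   lineterminator="\n")
    pd.DataFrame([report]).to_csv(output_dir / "prewas_mismatch_report.tsv",
                                  sep="\t", index=False, lineterminator="\n")
    if gene_matrices is not None:
        for name, gm in gene_matrices.items():
            safe = name.replace(":", "_").replace(",", "_")
            write_matrix(gm, output_dir / f"prewas_gene_{safe}.tsv")
    if recon is not None:
        _write_reconstruction_log(recon, output_dir / "prewas_ancestral_log.tsv")

    manifest = {
        "tool": "prewas",
        "version": __version__,
        "inputs": {"vcf": str(vcf), "tree": str(tree) if tree else None,
                   "outgroup": outgroup, "gff": str(gff) if gff else None},
        "parameters": {"mode": mode, "confidence_threshold": threshold,
                       "impact_subset": sorted(impact_subset)
                       if impact_subset else None, "seed": seed},
        "n_samples": len(table.samples),
        "n_sites": matrix.n_sites,
        "n_variant_rows": bvm.n_rows,
    }
    (output_dir / "prewas_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RunResult(allele_matrix=matrix, variant_matrix=bvm,
                     reference_log=ref_log, mismatch_report=report,
                     gene_matrices=gene_matrices, summary=summary,
                     output_dir=output_dir, reconstruction=recon)


def _write_reconstruction_log(recon, path: Path) -> None:
    rows = []
    for key, site in recon.sites.items():
        probs = ";".join(f"{s}:{p:.6g}" for s, p in site.root.probs.items())
        rows.append((key, ",".join(site.root.states), probs,
                     site.root.ml_state, site.root.confidence))
    pd.DataFrame(rows, columns=["site", "states", "probs", "ml_state",
                                "confidence"]
                 ).to_csv(path, sep="\t", index=False, lineterminator="\n")
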