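"""Ground-truthed synthetic fixtures: tree, evolved sites, VCF/GFF/newick.

Everything downstream of variant calling can be exercised with data whose
truth is known exactly: a random Yule tree, nucleotide sites evolved along
it under Jukes-Cantor with every substitution event recorded (giving true
root alleles and true per-edge state changes for convergence scoring),
post-hoc "N" masking to emulate missing calls, and serialisation to a
merged multi-sample VCF with synthetic SnpEff-style ANN annotations plus
a GFF3 with configurable overlapping genes.

Jukes-Cantor generates the data while the reconstruction under test uses
the equal-rates chain over observed states — the simulation truth about
real alleles is kept separate from the missing-data convention being
tested.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneRecord
from .phylo import IndexedTree, Phylogeny, index_tree

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
CONTIG = "contig1"

#: fraction of sites whose substitution rate is multiplied by
#: ``multiallelic_boost`` (enriches for multiallelic sites)
BOOST_FRACTION = 0.1


def simulate_tree(n_tips: int, seed: int, height: float = 0.1) -> Phylogeny:
    """Random Yule (pure-birth) tree scaled to a fixed root-to-tip height.

    Waiting times between speciation events are exponential; the lineage
    that splits is chosen uniformly.  All branch lengths are scaled so
    the maximum root-to-tip distance equals ``height`` (substitutions per
    site).  Deterministic per seed; tips are named ``t1..tn``.
    """
    if n_tips < 3:
        raise ValueError("tree requires >=3 tips")
    rng = np.random.default_rng(seed)

    # node = [children, pending branch length]
    root: list = [[], 0.0]
    active = [root]
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / len(active))
        for node in active:
            node[1] += dt
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        left, right = [[], 0.0], [[], 0.0]
        node[0] = [left, right]
        active.extend([left, right])
    dt = rng.exponential(1.0 / n_tips)
    for node in active:
        node[1] += dt

    tip_iter = iter(range(1, n_tips + 1))

    def depth(node) -> float:
        return node[1] + (max(depth(c) for c in node[0]) if node[0] else 0.0)

    # the root's own accumulated waiting time is not part of any tip path
    tip_height = max(depth(c) for c in root[0])
    scale = height / tip_height if tip_height > 0 else 1.0

    def to_newick(node) -> str:
        if not node[0]:
            return f"t{next(tip_iter)}:{node[1] * scale:.10f}"
        inner = ",".join(to_newick(c) for c in node[0])
        return f"({inner}):{node[1] * scale:.10f}"

    newick = f"({','.join(to_newick(c) for c in root[0])});"
    return Phylogeny.from_newick(newick)


@dataclasses.dataclass
class SiteTruth:
    """Ground truth for one simulated site."""

    root_allele: str
    node_states: dict[str, str]            # every node label -> true allele
    changes: list[tuple[str, str, str]]    # (child label, parent state, child state)

    def arisals(self) -> dict[str, int]:
        """True arisal count per allele from edge endpoint changes."""
        out: dict[str, int] = {}
        for _, _, child_state in self.changes:
            out[child_state] = out.get(child_state, 0) + 1
        return out


@dataclasses.dataclass
class SimulatedAlignment:
    """Evolved tip alleles ("N"-masked) plus the exact simulation truth."""

    phylogeny: Phylogeny
    samples: list[str]
    alignment: np.ndarray        # sites x samples, allele strings incl. "N"
    truth: list[SiteTruth]
    true_alignment: np.ndarray   # pre-masking tip states

    @property
    def n_sites(self) -> int:
        return self.alignment.shape[0]


def evolve_sites(phy: Phylogeny, n_sites: int, rate: float = 1.0,
                 missing_prob: float = 0.01, multiallelic_boost: float = 1.0,
                 seed: int = 0) -> SimulatedAlignment:
    """Evolve nucleotide sites along a rooted tree under Jukes-Cantor.

    Each site draws a uniform-random root allele; substitutions occur
    along each branch as a Poisson process with intensity ``rate`` per
    unit branch length, each event replacing the allele with one of the
    other three uniformly.  ``multiallelic_boost`` multiplies the rate of
    a fixed :data:`BOOST_FRACTION` of sites.  Tips are masked to "N" with
    probability ``missing_prob`` after evolution; the truth record keeps
    the real states and every per-edge state change.
    """
    if not phy.rooted:
        raise ValueError("evolution requires a rooted tree")
    rng = np.random.default_rng(seed)
    itree = index_tree(phy)
    n_nodes = len(itree.labels)
    leaf_idx = np.nonzero(itree.is_leaf)[0]
    samples = sorted((itree.labels[i] for i in leaf_idx),
                     key=lambda s: (len(s), s))

    rates = np.full(n_sites, rate, dtype=float)
    if multiallelic_boost != 1.0:
        boosted = rng.random(n_sites) < BOOST_FRACTION
        rates[boosted] *= multiallelic_boost

    preorder = list(itree.postorder[::-1])
    truth: list[SiteTruth] = []
    aln = np.empty((n_sites, len(samples)), dtype=object)
    true_aln = np.empty((n_sites, len(samples)), dtype=object)
    col = {s: j for j, s in enumerate(samples)}

    for s_i in range(n_sites):
        states = [""] * n_nodes
        root = itree.root
        states[root] = NUCLEOTIDES[int(rng.integers(4))]
        changes: list[tuple[str, str, str]] = []
        for node in preorder:
            p = itree.parent[node]
            if p < 0:
                continue
            allele = states[p]
            n_events = int(rng.poisson(rates[s_i] * itree.edge_length[node]))
            for _ in range(n_events):
                others = [b for b in NUCLEOTIDES if b != allele]
                allele = others[int(rng.integers(3))]
            states[node] = allele
            if allele != states[p]:
                changes.append((itree.labels[node], states[p], allele))
        node_states = {itree.labels[i]: states[i] for i in range(n_nodes)}
        truth.append(SiteTruth(root_allele=states[root],
                               node_states=node_states, changes=changes))
        for i in leaf_idx:
            true_aln[s_i, col[itree.labels[i]]] = states[i]
        mask = rng.random(len(samples)) < missing_prob
        for j in range(len(samples)):
            aln[s_i, j] = "N" if mask[j] else true_aln[s_i, j]

    return SimulatedAlignment(phylogeny=phy, samples=samples, alignment=aln,
                              truth=truth, true_alignment=true_aln)


def default_genes_spec(n_sites: int) -> list[GeneRecord]:
    """Two overlapping genes over the first 60 % of sites, one further gene.

    Positions are 1-based site indices; the overlap region guarantees
    variants assigned to two genes so overlap handling is exercised.
    """
    a_end = max(2, int(n_sites * 0.4))
    b_start = max(1, int(n_sites * 0.25))
    b_end = max(b_start + 1, int(n_sites * 0.6))
    c_start = min(n_sites, b_end + 2)
    return [
        GeneRecord("geneA", CONTIG, 1, a_end, "+"),
        GeneRecord("geneB", CONTIG, b_start, b_end, "-"),
        GeneRecord("geneC", CONTIG, c_start, n_sites, "+"),
    ]


def _impact_for(pos: int, alt: str, gene: str,
                impact_map: Mapping[tuple[int, str, str], str] | None,
                rng: np.random.Generator) -> str:
    from .alleles import IMPACT_CATEGORIES
    if impact_map is not None:
        return impact_map.get((pos, alt, gene)) or \
            IMPACT_CATEGORIES[int(rng.integers(4))]
    return IMPACT_CATEGORIES[int(rng.integers(4))]


def emit_fixture(sim: SimulatedAlignment, out_dir: str | Path,
                 genes: Sequence[GeneRecord] | None = None,
                 impact_map: Mapping[tuple[int, str, str], str] | None = None,
                 annotate: bool = True, seed: int = 0,
                 ref_mode: str = "root") -> dict[str, Path]:
    """Serialise a simulated alignment to VCF + GFF3 + newick + truth files.

    Site i is placed at position i+1 on a single contig.  The VCF REF
    allele is the true root allele (``ref_mode='root'``) or a uniform
    random nucleotide (``'random'``); ALT is every distinct observed
    non-"N", non-REF allele, sorted.  Sites with an empty ALT list are
    not emitted (flagged in the truth table).  ANN entries (one per
    alt x containing gene) carry the requested or random impact.
    Returns paths: vcf, gff, tree, truth_root, truth_events.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = default_genes_spec(sim.n_sites)

    if ref_mode not in ("root", "random"):
        raise ValueError("ref_mode must be 'root' or 'random'")
    refs = [t.root_allele if ref_mode == "root"
            else NUCLEOTIDES[int(rng.integers(4))] for t in sim.truth]

    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length={max(sim.n_sites, 1)}>",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
        'annotations: \'Allele | Annotation | Impact | Gene_Name | Gene_ID\'">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sim.samples),
    ]
    emitted = np.zeros(sim.n_sites, dtype=bool)
    for i in range(sim.n_sites):
        pos = i + 1
        row = sim.alignment[i]
        ref = refs[i]
        alts = sorted({a for a in row if a not in ("N", ref)})
        if not alts:
            continue
        emitted[i] = True
        idx = {a: k + 1 for k, a in enumerate(alts)}
        calls = ["." if a == "N" else str(idx.get(a, 0)) for a in row]
        info = "."
        if annotate:
            ann = []
            for alt in alts:
                for g in genes:
                    if g.chrom == CONTIG and g.start <= pos <= g.end:
                        imp = _impact_for(pos, alt, g.gene_id, impact_map, rng)
                        ann.append(
                            f"{alt}|variant|{imp}|{g.gene_id}|{g.gene_id}")
            if ann:
                info = "ANN=" + ",".join(ann)
        vcf_lines.append(
            f"{CONTIG}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\t{info}\t"
            "GT\t" + "\t".join(calls))

    paths = {
        "vcf": out_dir / "fixture.vcf",
        "gff": out_dir / "fixture.gff",
        "tree": out_dir / "fixture.nwk",
        "truth_root": out_dir / "truth_root.tsv",
        "truth_events": out_dir / "truth_events.tsv",
    }
    paths["vcf"].write_text("\n".join(vcf_lines) + "\n")
    gff_lines = ["##gff-version 3"] + [
        f"{g.chrom}\tprewas_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
        f"ID={g.gene_id}" for g in genes
    ]
    paths["gff"].write_text("\n".join(gff_lines) + "\n")
    paths["tree"].write_text(sim.phylogeny.newick())

    pd.DataFrame({
        "pos": np.arange(1, sim.n_sites + 1),
        "root_allele": [t.root_allele for t in sim.truth],
        "ref_genome": refs,
        "emitted": emitted.astype(int),
    }).to_csv(paths["truth_root"], sep="\t", index=False)
    events = [(i + 1, child, ps, cs)
              for i, t in enumerate(sim.truth)
              for child, ps, cs in t.changes]
    pd.DataFrame(events, columns=["pos", "child", "parent_state",
                                  "child_state"]
                 ).to_csv(paths["truth_events"], sep="\t", index=False)
    return paths
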