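"""Phylogenetic machinery: tree building, rooting and ancestral reconstruction.

The re-referencing step of the pre-processing workflow needs, for every
variant site, the maximum-likelihood allele at the root of the sample
phylogeny.  This module provides

* a thin :class:`Phylogeny` wrapper around :class:`dendropy.Tree`,
* neighbour-joining tree construction from SNP Hamming distances (a
  convenience fallback when the user supplies no tree),
* outgroup / midpoint rooting,
* marginal maximum-likelihood ancestral state reconstruction under an
  equal-rates (ER) continuous-time Markov chain, computed with the
  Felsenstein pruning algorithm, and
* allele convergence (homoplasy) counting on the reconstructed states.

Missing data ("N") deliberately participates as a real fifth character
state in the chain — the workflow treats missing data as a competing
allele so that a site whose root is most likely "missing" can be detected
and removed, rather than imputed.
"""

from __future__ import annotations

import dataclasses
import io as _io
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: states are sorted alphabetically everywhere; argmax ties therefore
#: resolve to the alphabetically first state, deterministically.
_ZERO_BRANCH_FRACTION = 1e-9


class PhyloError(ValueError):
    """Raised for invalid tree inputs or tree/sample mismatches."""


@dataclasses.dataclass
class Phylogeny:
    """A rooted or unrooted tree with named tips and branch lengths >= 0."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def rooted(self) -> bool:
        """A basal bifurcation is taken as evidence of rootedness."""
        return len(self.tree.seed_node.child_nodes()) == 2

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True)
        return s.strip() + "\n"

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)


# ---------------------------------------------------------------------------
# tree construction and rooting
# ---------------------------------------------------------------------------

def hamming_distance_matrix(cells: np.ndarray, samples: Sequence[str]) -> np.ndarray:
    """Pairwise Hamming distances over sites where both samples are non-"N".

    ``cells`` is a sites x samples array of allele strings.  The distance is
    mismatches / compared sites; a pair with zero comparable sites gets
    distance 0 with a warning.
    """
    n = len(samples)
    valid = cells != "N"
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[:, i] & valid[:, j]
            m = int(both.sum())
            if m == 0:
                warnings.warn(
                    f"samples {samples[i]!r} and {samples[j]!r} share no "
                    "comparable sites; distance set to 0"
                )
                dij = 0.0
            else:
                dij = float((cells[both, i] != cells[both, j]).sum()) / m
            d[i, j] = d[j, i] = dij
    return d


def build_nj_tree(matrix) -> Phylogeny:
    """Neighbour-joining tree from an :class:`~prewas.alleles.AlleleMatrix`.

    Deterministic for a given sample order; negative NJ branch lengths are
    clamped to zero.  Intended as a fallback — an externally estimated ML
    tree is preferable for ancestral reconstruction.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    samples = list(matrix.samples)
    if len(samples) < 3:
        raise PhyloError("tree requires >=3 samples")
    cells = matrix.values()
    d = hamming_distance_matrix(cells, samples)
    dm = DistanceMatrix(d, ids=samples)
    sk_tree = nj(dm)
    buf = _io.StringIO()
    sk_tree.write(buf)
    phy = Phylogeny.from_newick(buf.getvalue())
    for edge in phy.tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    logger.info("built NJ tree with %d tips; a user-supplied ML tree is "
                "preferred when available", len(samples))
    return phy


def root_tree(phy: Phylogeny, outgroup: str | None = None) -> Phylogeny:
    """Root a tree, optionally on an outgroup tip.

    With an outgroup the tree is rooted at the attachment point of the
    branch leading to the outgroup and the outgroup tip is then pruned —
    its only role is to orient the root.  Without an outgroup an unrooted
    tree is midpoint-rooted; an already-rooted tree is returned unchanged
    (as a copy).
    """
    phy = phy.copy()
    tree = phy.tree
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise PhyloError(f"outgroup {outgroup!r} is not a tip of the tree")
        parent = node.parent_node
        if parent is not tree.seed_node:
            tree.reroot_at_node(parent, update_bipartitions=False)
        tree.prune_taxa_with_labels([outgroup], suppress_unifurcations=True)
        # pruning can leave a unifurcate seed; collapse it
        while len(tree.seed_node.child_nodes()) == 1:
            tree.seed_node = tree.seed_node.child_nodes()[0]
            tree.seed_node.parent_node = None
        tree.seed_node.edge.length = None
        return phy
    if not phy.rooted:
        tree.reroot_at_midpoint(update_bipartitions=False)
    return phy


def prepare_tree(phy: Phylogeny, samples: Sequence[str],
                 outgroup: str | None = None) -> Phylogeny:
    """Validate, root and restrict a tree to the VCF sample set.

    The tree's tips must be a superset of ``samples``; extra tips (beyond
    the outgroup) are pruned with a warning so that, after preparation,
    the tip set equals the sample set exactly.
    """
    tips = set(phy.tip_labels)
    missing = sorted(set(samples) - tips)
    if missing:
        raise PhyloError(
            "tree is missing sample tips: " + ", ".join(missing))
    phy = root_tree(phy, outgroup=outgroup)
    extra = sorted(set(phy.tip_labels) - set(samples))
    if extra:
        warnings.warn(f"pruning {len(extra)} tree tips absent from the VCF: "
                      + ", ".join(extra))
        phy.tree.prune_taxa_with_labels(extra, suppress_unifurcations=True)
        while len(phy.tree.seed_node.child_nodes()) == 1:
            phy.tree.seed_node = phy.tree.seed_node.child_nodes()[0]
            phy.tree.seed_node.parent_node = None
    return phy


# ---------------------------------------------------------------------------
# indexed tree for likelihood computations
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IndexedTree:
    """Array representation of a rooted tree for pruning computations.

    Nodes are numbered in postorder (root last).  Internal nodes are given
    stable labels ``node_<i>`` (written back onto the dendropy tree) so that
    reconstruction output can be matched to tree edges later.
    """

    labels: list[str]            # per node: tip label or internal label
    parent: np.ndarray           # parent index, -1 for root
    children: list[list[int]]
    edge_length: np.ndarray      # branch length above each node (0 for root)
    is_leaf: np.ndarray
    postorder: np.ndarray        # node indices, root last

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def tip_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in np.nonzero(self.is_leaf)[0]}

    @property
    def internal_labels(self) -> list[str]:
        return [self.labels[i] for i in np.nonzero(~self.is_leaf)[0]]

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs, tips included as children."""
        return [(int(self.parent[i]), i)
                for i in range(len(self.labels)) if self.parent[i] >= 0]


def index_tree(phy: Phylogeny) -> IndexedTree:
    if not phy.rooted:
        raise PhyloError("ancestral reconstruction requires a rooted tree")
    nodes = list(phy.tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    labels, parent, lengths, leaf, children = [], [], [], [], []
    n_internal = 0
    for n in nodes:
        if n.is_leaf():
            labels.append(n.taxon.label)
            leaf.append(True)
        else:
            if not n.label:
                n.label = f"node_{n_internal}"
            labels.append(n.label)
            leaf.append(False)
            n_internal += 1
        parent.append(idx[id(n.parent_node)] if n.parent_node else -1)
        lengths.append(float(n.edge.length or 0.0) if n.parent_node else 0.0)
        children.append([idx[id(c)] for c in n.child_nodes()])
    return IndexedTree(
        labels=labels,
        parent=np.asarray(parent, dtype=int),
        children=children,
        edge_length=np.asarray(lengths, dtype=float),
        is_leaf=np.asarray(leaf, dtype=bool),
        postorder=np.arange(len(nodes)),
    )


# ---------------------------------------------------------------------------
# ER likelihood and marginal reconstruction
# ---------------------------------------------------------------------------

def _er_transition(rate: float, t: float, k: int) -> np.ndarray:
    """Transition matrix of the k-state equal-rates chain after time t.

    Off-diagonal rate ``rate``; P(t) has the closed form
    p_same = 1/k + (k-1)/k * exp(-k r t), p_diff = (1 - exp(-k r t))/k.
    """
    e = np.exp(-k * rate * t)
    p_diff = (1.0 - e) / k
    p = np.full((k, k), p_diff)
    np.fill_diagonal(p, 1.0 / k + (k - 1) / k * e)
    return p


def _effective_lengths(itree: IndexedTree) -> np.ndarray:
    """Branch lengths with zeros nudged for numerical stability."""
    lengths = itree.edge_length.copy()
    height = _tree_height(itree)
    if height > 0:
        eps = _ZERO_BRANCH_FRACTION * height
        nonroot = itree.parent >= 0
        lengths[nonroot & (lengths <= 0)] = eps
    return lengths


def _tree_height(itree: IndexedTree) -> float:
    depth = np.zeros(len(itree.labels))
    for i in itree.postorder[::-1]:
        p = itree.parent[i]
        if p >= 0:
            depth[i] = depth[p] + itree.edge_length[i]
    return float(depth[itree.is_leaf].max()) if itree.is_leaf.any() else 0.0


def _pruning_pass(itree: IndexedTree, lengths: np.ndarray,
                  tip_state_idx: np.ndarray, k: int, rate: float):
    """Down (postorder) conditional likelihoods with per-node rescaling.

    Returns (partials, log_scale, messages) where ``messages[child]`` is
    P(t_child) @ partial(child), the contribution a child passes up.
    """
    n = len(itree.labels)
    partial = np.zeros((n, k))
    messages = [None] * n
    log_scale = 0.0
    for i in itree.postorder:
        if itree.is_leaf[i]:
            partial[i, tip_state_idx[i]] = 1.0
        else:
            acc = np.ones(k)
            for c in itree.children[i]:
                p = _er_transition(rate, lengths[c], k)
                msg = p @ partial[c]
                messages[c] = (p, msg)
                acc *= msg
            s = acc.max()
            if s <= 0:
                return None, -np.inf, messages
            partial[i] = acc / s
            log_scale += np.log(s)
    return partial, log_scale, messages


def site_log_likelihood(itree: IndexedTree, tip_states: Mapping[str, str],
                        states: Sequence[str], rate: float,
                        lengths: np.ndarray | None = None) -> float:
    """Felsenstein-pruning log-likelihood of one site under the ER model.

    ``states`` must be sorted and cover every tip state; the root prior is
    flat over ``states``.
    """
    k = len(states)
    state_to_idx = {s: i for i, s in enumerate(states)}
    tip_idx = np.zeros(len(itree.labels), dtype=int)
    for lab, i in itree.tip_index.items():
        tip_idx[i] = state_to_idx[tip_states[lab]]
    if lengths is None:
        lengths = _effective_lengths(itree)
    partial, log_scale, _ = _pruning_pass(itree, lengths, tip_idx, k, rate)
    if partial is None:
        return -np.inf
    lik = partial[itree.root] @ np.full(k, 1.0 / k)
    return float(np.log(lik) + log_scale)


@dataclasses.dataclass
class RootDistribution:
    """Scaled marginal likelihoods of each state at the tree root."""

    site_key: str
    states: tuple[str, ...]
    probs: dict[str, float]
    ml_state: str
    confidence: float


@dataclasses.dataclass
class SiteReconstruction:
    root: RootDistribution
    node_states: dict[str, str]   # internal-node label -> ML state
    rate: float


@dataclasses.dataclass
class ReconstructionResult:
    """Per-site marginal ML ancestral reconstruction over one tree."""

    phylogeny: Phylogeny
    itree: IndexedTree
    sites: dict[str, SiteReconstruction]

    def root_distribution(self, site_key: str) -> RootDistribution:
        return self.sites[site_key].root

    def node_states(self, site_key: str) -> dict[str, str]:
        return self.sites[site_key].node_states


def _reconstruct_pattern(itree: IndexedTree, lengths: np.ndarray,
                         pattern: tuple[str, ...], tip_order: Sequence[str],
                         rate_bounds=(1e-8, 100.0), xatol=1e-8):
    """Fit the ER rate and compute marginal state probabilities.

    Returns (states, root_probs, node_argmax, rate).  ``pattern`` is the
    tip state tuple in ``tip_order``; the state space is the set of
    observed states, sorted.
    """
    states = tuple(sorted(set(pattern)))
    k = len(states)
    tip_states = dict(zip(tip_order, pattern))
    n = len(itree.labels)
    internal = np.nonzero(~itree.is_leaf)[0]

    if k == 1:
        probs = np.array([1.0])
        node_states = {itree.labels[i]: states[0] for i in internal}
        return states, probs, node_states, 0.0

    state_to_idx = {s: i for i, s in enumerate(states)}
    tip_idx = np.zeros(n, dtype=int)
    for lab, i in itree.tip_index.items():
        tip_idx[i] = state_to_idx[tip_states[lab]]

    if lengths[itree.parent >= 0].max(initial=0.0) <= 0:
        warnings.warn("zero-length tree: rate fit degenerate, using a "
                      "uniform root distribution")
        probs = np.full(k, 1.0 / k)
        node_states = {itree.labels[i]: states[0] for i in internal}
        return states, probs, node_states, float("nan")

    def neg_loglik(log_rate: float) -> float:
        partial, log_scale, _ = _pruning_pass(
            itree, lengths, tip_idx, k, float(np.exp(log_rate)))
        if partial is None:
            return np.inf
        lik = partial[itree.root].mean()
        if lik <= 0:
            return np.inf
        return -(np.log(lik) + log_scale)

    res = minimize_scalar(neg_loglik,
                          bounds=(np.log(rate_bounds[0]), np.log(rate_bounds[1])),
                          method="bounded", options={"xatol": xatol})
    rate = float(np.exp(res.x))

    partial, _, messages = _pruning_pass(itree, lengths, tip_idx, k, rate)
    prior = np.full(k, 1.0 / k)

    # upward pass: marginal(v) ∝ partial(v) * outside(v)
    outside = np.zeros((n, k))
    root = itree.root
    outside[root] = prior
    for i in itree.postorder[::-1]:
        if itree.is_leaf[i]:
            continue
        sib_prod = {}
        msgs = [messages[c][1] for c in itree.children[i]]
        full = np.prod(msgs, axis=0)
        for ci, c in enumerate(itree.children[i]):
            with np.errstate(divide="ignore", invalid="ignore"):
                others = np.where(msgs[ci] > 0, full / msgs[ci], 0.0)
            # recompute exactly when any message element is zero
            if (msgs[ci] <= 0).any():
                others = np.ones(k)
                for cj, m in enumerate(msgs):
                    if cj != ci:
                        others *= m
            sib_prod[c] = others
        for c in itree.children[i]:
            p_c = messages[c][0]
            out = (outside[i] * sib_prod[c]) @ p_c
            s = out.max()
            outside[c] = out / s if s > 0 else out

    root_marg = partial[root] * prior
    root_marg = root_marg / root_marg.sum()
    node_states = {}
    for i in internal:
        if i == root:
            marg = root_marg
        else:
            marg = partial[i] * outside[i]
            tot = marg.sum()
            marg = marg / tot if tot > 0 else np.full(k, 1.0 / k)
        node_states[itree.labels[i]] = states[int(np.argmax(marg))]
    return states, root_marg, node_states, rate


def reconstruct_root(matrix, phy: Phylogeny,
                     rate_bounds=(1e-8, 100.0)) -> ReconstructionResult:
    """Marginal ML ancestral reconstruction for every site of a matrix.

    For each site the state space is the set of observed tip states at that
    site ("N" included when present, as a real fifth allele).  A single ER
    rate is fitted per site by bounded 1-D likelihood maximisation; the
    root distribution is the scaled marginal likelihood under a flat root
    prior.  Sites sharing a tip-state pattern are computed once.
    """
    samples = list(matrix.samples)
    tipset = set(phy.tip_labels)
    if tipset != set(samples):
        raise PhyloError("tree tip set must equal the sample set; run "
                         "prepare_tree first")
    itree = index_tree(phy)
    lengths = _effective_lengths(itree)
    cells = matrix.values()
    site_keys = list(matrix.site_keys())

    # matrix column order may differ from tip order; build per-site pattern
    col = {s: j for j, s in enumerate(samples)}
    tip_order = sorted(samples)
    order = [col[s] for s in tip_order]

    cache: dict[tuple[str, ...], tuple] = {}
    sites: dict[str, SiteReconstruction] = {}
    for r, key in enumerate(site_keys):
        pattern = tuple(cells[r, order])
        if pattern not in cache:
            cache[pattern] = _reconstruct_pattern(
                itree, lengths, pattern, tip_order, rate_bounds=rate_bounds)
        states, probs, node_states, rate = cache[pattern]
        probs_d = {s: float(p) for s, p in zip(states, probs)}
        ml = states[int(np.argmax(probs))]
        sites[key] = SiteReconstruction(
            root=RootDistribution(site_key=key, states=states, probs=probs_d,
                                  ml_state=ml,
                                  confidence=float(np.max(probs))),
            node_states=dict(node_states),
            rate=rate,
        )
    return ReconstructionResult(phylogeny=phy, itree=itree, sites=sites)


# ---------------------------------------------------------------------------
# convergence counting
# ---------------------------------------------------------------------------

def count_convergence(tip_states: Mapping[str, str],
                      node_states: Mapping[str, str],
                      itree: IndexedTree) -> dict[str, int]:
    """Number of convergence events per allele: arisals minus one, floored at 0.

    An arisal is a tree edge (parent -> child, tips counted as children)
    where the parent's reconstructed state differs from the allele and the
    child's state equals it.  An allele that equals the root state and
    occupies a single contiguous domain never re-arises and scores 0.
    """
    def state_of(i: int) -> str:
        lab = itree.labels[i]
        return tip_states[lab] if itree.is_leaf[i] else node_states[lab]

    alleles = set(tip_states.values()) | set(node_states.values())
    arisals = {a: 0 for a in alleles}
    for p, c in itree.edges():
        sp, sc = state_of(p), state_of(c)
        if sp != sc:
            arisals[sc] += 1
    return {a: max(n - 1, 0) for a, n in arisals.items()}
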