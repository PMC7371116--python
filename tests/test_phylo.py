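import numpy as np
import pytest

from prewas import phylo
from prewas.phylo import (Phylogeny, build_nj_tree, count_convergence,
                          index_tree, prepare_tree, reconstruct_root,
                          root_tree, site_log_likelihood, _effective_lengths)

from conftest import make_allele_matrix
from _oracles import enumeration_site_loglik


def leaf_depths(phy):
    depths = {}
    for leaf in phy.tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def clades_at_root(phy):
    return sorted(
        sorted(l.taxon.label for l in c.leaf_iter())
        for c in phy.tree.seed_node.child_nodes())


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(A,B)=0.1, d(A,C)=d(B,C)=0.4 over 10 sites
        rows = []
        seqs = {"A": "AAAAAAAAAA", "B": "AAAAAAAAAG", "C": "CCCAAAAAAT"}
        for i in range(10):
            rows.append([seqs[s][i] for s in ("A", "B", "C")])
        m = make_allele_matrix(rows, samples=["A", "B", "C"])
        phy = build_nj_tree(m)
        rooted = root_tree(phy)  # midpoint falls on C's long branch
        assert clades_at_root(rooted) == [["A", "B"], ["C"]]
        # closed-form terminal branch lengths of the 3-taxon star
        d = {l.taxon.label: l.edge.length for l in phy.tree.leaf_node_iter()}
        assert d["A"] == pytest.approx(0.05)
        assert d["B"] == pytest.approx(0.05)
        assert d["C"] == pytest.approx(0.35)

    def test_four_taxon_additive_recovery_vs_least_squares(self):
        # alignment realising an additive AB|CD metric over 6 sites
        rows = [list(r) for r in
                ["GAAA", "AGAA", "AAGA", "AAAG", "GGAA", "GGAA"]]
        samples = ["A", "B", "C", "D"]
        m = make_allele_matrix(rows, samples=samples)
        phy = build_nj_tree(m)
        # oracle: least-squares fit of each unrooted 4-taxon topology
        from prewas.phylo import hamming_distance_matrix
        d = hamming_distance_matrix(m.values(), samples)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        y = np.array([d[i, j] for i, j in pairs])
        splits = {"AB|CD": ({0, 1}, {2, 3}), "AC|BD": ({0, 2}, {1, 3}),
                  "AD|BC": ({0, 3}, {1, 2})}
        resid = {}
        for name, (left, _) in splits.items():
            # edges: 4 terminal + 1 internal; d(i,j) = e_i + e_j (+ m across)
            X = np.zeros((6, 5))
            for r, (i, j) in enumerate(pairs):
                X[r, i] = X[r, j] = 1
                if (i in left) != (j in left):
                    X[r, 4] = 1
            fit, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid[name] = float(((X @ fit - y) ** 2).sum())
        assert min(resid, key=resid.get) == "AB|CD"
        # NJ tree must contain the AB|CD split
        for node in phy.tree.preorder_internal_node_iter():
            if node is phy.tree.seed_node:
                continue
            leaves = sorted(l.taxon.label for l in node.leaf_iter())
            if len(leaves) == 2:
                assert leaves in (["A", "B"], ["C", "D"])

    def test_identical_samples_star_with_zero_branches(self):
        m = make_allele_matrix([["A", "A", "A", "A"], ["G", "G", "G", "G"]],
                               samples=list("WXYZ"))
        phy = build_nj_tree(m)
        assert all((e.length or 0.0) == 0.0
                   for e in phy.tree.preorder_edge_iter())

    def test_requires_three_samples(self):
        m = make_allele_matrix([["A", "G"]], samples=["a", "b"])
        with pytest.raises(phylo.PhyloError, match=">=3"):
            build_nj_tree(m)

    def test_disjoint_missingness_warns_distance_zero(self):
        m = make_allele_matrix([["A", "N", "A"], ["N", "G", "G"]],
                               samples=["a", "b", "c"])
        with pytest.warns(UserWarning, match="no comparable sites"):
            phylo.hamming_distance_matrix(m.values(), m.samples)


class TestRooting:
    def test_outgroup_roots_then_prunes(self):
        phy = Phylogeny.from_newick("(A:1,B:1,C:2);")
        rooted = root_tree(phy, outgroup="C")
        assert sorted(rooted.tip_labels) == ["A", "B"]
        assert rooted.rooted

    def test_already_rooted_unchanged_without_outgroup(self):
        phy = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        assert root_tree(phy).newick() == phy.newick()

    def test_midpoint_halves_longest_path(self):
        phy = Phylogeny.from_newick("(X:4,M:1,Y:6);")
        rooted = root_tree(phy)
        depths = leaf_depths(rooted)
        assert depths["X"] == pytest.approx(5.0)
        assert depths["Y"] == pytest.approx(5.0)

    def test_unknown_outgroup_rejected(self):
        phy = Phylogeny.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(phylo.PhyloError, match="outgroup"):
            root_tree(phy, outgroup="Z")

    def test_prepare_prunes_extra_tips(self):
        phy = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.warns(UserWarning, match="pruning"):
            out = prepare_tree(phy, ["A", "B", "C"])
        assert sorted(out.tip_labels) == ["A", "B", "C"]


class TestReconstruction:
    def test_monomorphic_site_is_certain(self):
        phy = Phylogeny.from_newick("((a:1,b:1):1,c:2);")
        m = make_allele_matrix([["A", "A", "A"]], samples=["a", "b", "c"])
        res = reconstruct_root(m, phy)
        dist = res.root_distribution("1")
        assert dist.probs == {"A": 1.0}
        assert dist.confidence == 1.0

    def test_two_tip_symmetry_gives_half_half(self):
        phy = Phylogeny.from_newick("(a:1,b:1);")
        m = make_allele_matrix([["A", "G"]], samples=["a", "b"])
        dist = reconstruct_root(m, phy).root_distribution("1")
        assert dist.probs["A"] == pytest.approx(0.5, abs=1e-9)
        assert dist.probs["G"] == pytest.approx(0.5, abs=1e-9)
        assert dist.ml_state == "A"  # alphabetical tie-break

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_equals_enumeration_on_six_tips(self, seed):
        rng = np.random.default_rng(seed)
        phy = __import__("prewas.simulate", fromlist=["x"]).simulate_tree(
            6, seed=seed, height=float(rng.uniform(0.05, 1.5)))
        itree = index_tree(phy)
        states = ["A", "C", "G", "N"][: int(rng.integers(2, 5))]
        tips = {t: states[int(rng.integers(len(states)))]
                for t in phy.tip_labels}
        if len(set(tips.values())) < 2:
            tips[phy.tip_labels[0]] = [s for s in states
                                       if s != tips[phy.tip_labels[1]]][0]
        used = tuple(sorted(set(tips.values())))
        rate = float(rng.uniform(0.05, 5.0))
        lengths = _effective_lengths(itree)
        got = site_log_likelihood(itree, tips, used, rate, lengths=lengths)
        want = enumeration_site_loglik(itree, tips, used, rate, lengths)
        assert got == pytest.approx(want, rel=1e-9)

    def test_probs_sum_to_one_and_order_invariance(self):
        phy = Phylogeny.from_newick(
            "((a:0.1,b:0.2):0.1,((c:0.3,d:0.1):0.2,e:0.4):0.1);")
        rows = [["A", "A", "G", "G", "N"], ["C", "T", "C", "T", "C"]]
        samples = ["a", "b", "c", "d", "e"]
        m = make_allele_matrix(rows, samples=samples)
        res = reconstruct_root(m, phy)
        perm = [3, 1, 4, 0, 2]
        m2 = make_allele_matrix([[r[j] for j in perm] for r in rows],
                                samples=[samples[j] for j in perm])
        res2 = reconstruct_root(m2, phy)
        for key in ("1", "2"):
            p1 = res.root_distribution(key).probs
            p2 = res2.root_distribution(key).probs
            assert sum(p1.values()) == pytest.approx(1.0, abs=1e-9)
            for s in p1:
                assert p1[s] == pytest.approx(p2[s], abs=1e-12)

    def test_zero_length_tree_falls_back_to_uniform(self):
        phy = Phylogeny.from_newick("((a:0,b:0):0,c:0);")
        m = make_allele_matrix([["A", "G", "A"]], samples=["a", "b", "c"])
        with pytest.warns(UserWarning, match="zero-length"):
            dist = reconstruct_root(m, phy).root_distribution("1")
        assert dist.confidence == pytest.approx(0.5)

    def test_pattern_cache_shares_identical_sites(self):
        phy = Phylogeny.from_newick("((a:1,b:1):1,c:2);")
        rows = [["A", "A", "G"], ["A", "A", "G"]]
        m = make_allele_matrix(rows, samples=["a", "b", "c"])
        res = reconstruct_root(m, phy)
        assert res.root_distribution("1").probs == \
            res.root_distribution("2").probs

    def test_missing_state_participates_as_fifth_allele(self):
        # N-dominated tips with the single real allele on a long branch
        phy = Phylogeny.from_newick(
            "((a:0.01,b:0.01):0.01,(c:0.01,d:2.0):0.01);")
        m = make_allele_matrix([["N", "N", "N", "A"]],
                               samples=["a", "b", "c", "d"])
        dist = reconstruct_root(m, phy).root_distribution("1")
        assert set(dist.states) == {"A", "N"}
        assert dist.ml_state == "N"
        assert dist.probs["N"] > dist.probs["A"]


class TestConvergence:
    def tree4(self):
        phy = Phylogeny.from_newick("((t1:1,t2:1)n1:1,(t3:1,t4:1)n2:1)r;")
        return index_tree(phy)

    def test_single_origin_scores_zero(self):
        itree = self.tree4()
        tips = {"t1": "G", "t2": "G", "t3": "A", "t4": "A"}
        nodes = {"n1": "G", "n2": "A", "r": "A"}
        conv = count_convergence(tips, nodes, itree)
        assert conv["G"] == 0

    def test_two_disjoint_arisals_score_one(self):
        itree = self.tree4()
        tips = {"t1": "G", "t2": "A", "t3": "G", "t4": "A"}
        nodes = {"n1": "A", "n2": "A", "r": "A"}
        conv = count_convergence(tips, nodes, itree)
        assert conv["G"] == 1

    def test_root_allele_with_contiguous_domain_scores_zero(self):
        itree = self.tree4()
        tips = {"t1": "A", "t2": "A", "t3": "A", "t4": "T"}
        nodes = {"n1": "A", "n2": "A", "r": "A"}
        conv = count_convergence(tips, nodes, itree)
        assert conv["A"] == 0
        assert conv["T"] == 0
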