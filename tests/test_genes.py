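import numpy as np
import pandas as pd
import pytest

from prewas.binarize import binarize_all
from prewas.genes import assign_to_genes, collapse_to_genes, impact_matrix_suite
from prewas.io import GeneRecord
from prewas.referencing import select_references

from conftest import make_allele_matrix, random_allele_matrix
from _oracles import naive_gene_or


def bvm_from_rows(rows, chrom="contig1"):
    m = make_allele_matrix(rows, chrom=chrom)
    refs, _ = select_references(m, "major")
    return binarize_all(m, refs)


GENES = [GeneRecord("geneA", "contig1", 10, 50, "+"),
         GeneRecord("geneB", "contig1", 40, 90, "-")]


def bvm_at_positions(positions, pattern=("A", "G", "G", "A")):
    rows = [list(pattern) for _ in positions]
    m = make_allele_matrix(rows)
    m.sites["pos"] = list(positions)
    m.sites["key"] = [str(p) for p in positions]
    refs, _ = select_references(m, "major")
    return binarize_all(m, refs)


class TestAssignToGenes:
    def test_overlap_region_assigns_to_both_genes(self):
        bvm = bvm_at_positions([45])
        assignment, intergenic = assign_to_genes(bvm, GENES)
        assert assignment.values.tolist() == [["45.G", "geneA"],
                                              ["45.G", "geneB"]]
        assert intergenic == []

    def test_outside_all_genes_is_intergenic(self):
        bvm = bvm_at_positions([5])
        assignment, intergenic = assign_to_genes(bvm, GENES)
        assert assignment.empty
        assert intergenic == ["5.G"]

    def test_boundaries_are_inclusive(self):
        bvm = bvm_at_positions([10, 50, 51])
        assignment, _ = assign_to_genes(bvm, GENES)
        by_row = assignment.groupby("row_key")["gene"].apply(list).to_dict()
        assert by_row["10.G"] == ["geneA"]
        assert by_row["50.G"] == ["geneA", "geneB"]
        assert by_row["51.G"] == ["geneB"]

    def test_contig_mismatch_never_assigns(self):
        bvm = bvm_at_positions([45])
        genes = [GeneRecord("geneX", "other", 1, 100, "+")]
        assignment, intergenic = assign_to_genes(bvm, genes)
        assert assignment.empty and intergenic == ["45.G"]


class TestCollapseToGenes:
    def test_or_of_assigned_rows(self):
        bvm = bvm_at_positions([11, 12])
        bvm.data.iloc[0] = [0, 1, 0, 0]
        bvm.data.iloc[1] = [1, 0, 0, 0]
        assignment, _ = assign_to_genes(bvm, GENES)
        gm = collapse_to_genes(bvm, assignment)
        assert gm.loc["geneA"].tolist() == [1, 1, 0, 0]

    def test_single_row_gene_is_identity(self):
        bvm = bvm_at_positions([11])
        assignment, _ = assign_to_genes(bvm, GENES)
        gm = collapse_to_genes(bvm, assignment)
        assert gm.loc["geneA"].tolist() == bvm.data.iloc[0].tolist()

    def test_matches_or_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            m = random_allele_matrix(rng)
            n = m.n_sites
            m.sites["pos"] = list(range(1, n + 1))
            refs, _ = select_references(m, "major")
            bvm = binarize_all(m, refs)
            genes = [GeneRecord("gA", "contig1", 1, max(2, n // 2), "+"),
                     GeneRecord("gB", "contig1", max(1, n // 3), n, "-")]
            assignment, _ = assign_to_genes(bvm, genes)
            gm = collapse_to_genes(bvm, assignment)
            oracle = naive_gene_or(bvm, list(map(tuple, assignment.values)))
            assert list(gm.index) == sorted(oracle)
            for g, vec in oracle.items():
                assert gm.loc[g].tolist() == vec


class TestImpactSuite:
    def impacts(self, bvm, mapping):
        rows = []
        meta = bvm.meta.set_index("row_key")
        for (row_key, gene), impact in mapping.items():
            r = meta.loc[row_key]
            rows.append((r["chrom"], r["pos"], r["alt"], gene, impact))
        return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "gene",
                                           "impact"])

    def test_per_gene_impact_on_overlapping_pair(self):
        bvm = bvm_at_positions([45])
        assignment, _ = assign_to_genes(bvm, GENES)
        impacts = self.impacts(bvm, {("45.G", "geneA"): "HIGH",
                                     ("45.G", "geneB"): "LOW"})
        suite = impact_matrix_suite(bvm, assignment, impacts)
        assert list(suite["HIGH"].index) == ["geneA"]
        assert list(suite["LOW"].index) == ["geneB"]
        assert list(suite["MODERATE"].index) == []

    def test_custom_subset_is_union(self):
        bvm = bvm_at_positions([11, 45])
        assignment, _ = assign_to_genes(bvm, GENES)
        impacts = self.impacts(bvm, {("11.G", "geneA"): "HIGH",
                                     ("45.G", "geneA"): "MODERATE",
                                     ("45.G", "geneB"): "LOW"})
        suite = impact_matrix_suite(bvm, assignment, impacts,
                                    custom=["HIGH", "MODERATE"])
        key = "CUSTOM:HIGH,MODERATE"
        expected = (suite["HIGH"].reindex(["geneA"], fill_value=0)
                    | suite["MODERATE"].reindex(["geneA"], fill_value=0))
        assert suite[key].equals(expected.astype(suite[key].dtypes.iloc[0]))

    def test_empty_impacts_gives_only_all(self):
        bvm = bvm_at_positions([45])
        assignment, _ = assign_to_genes(bvm, GENES)
        suite = impact_matrix_suite(bvm, assignment,
                                    pd.DataFrame(columns=["chrom", "pos",
                                                          "alt", "gene",
                                                          "impact"]))
        assert list(suite) == ["ALL"]

    def test_unknown_custom_category_rejected(self):
        bvm = bvm_at_positions([45])
        assignment, _ = assign_to_genes(bvm, GENES)
        impacts = self.impacts(bvm, {("45.G", "geneA"): "HIGH"})
        with pytest.raises(ValueError, match="unknown impact"):
            impact_matrix_suite(bvm, assignment, impacts, custom=["SEVERE"])

    def test_subset_matrices_entrywise_below_all(self):
        rng = np.random.default_rng(9)
        m = random_allele_matrix(rng)
        n = m.n_sites
        refs, _ = select_references(m, "major")
        bvm = binarize_all(m, refs)
        genes = [GeneRecord("gA", "contig1", 1, n, "+"),
                 GeneRecord("gB", "contig1", 1, n // 2, "-")]
        assignment, _ = assign_to_genes(bvm, genes)
        mapping = {}
        cats = ["HIGH", "MODERATE", "LOW", "MODIFIER"]
        for i, (rk, g) in enumerate(map(tuple, assignment.values)):
            mapping[(rk, g)] = cats[i % 4]
        suite = impact_matrix_suite(bvm, assignment, self.impacts(bvm, mapping))
        all_m = suite["ALL"]
        for cat in cats:
            sub = suite[cat].reindex(index=all_m.index, columns=all_m.columns,
                                     fill_value=0)
            assert (sub.values <= all_m.values).all()

    def test_shrinking_overlap_never_increases_entries(self):
        bvm = bvm_at_positions([45, 60])
        wide = [GeneRecord("gA", "contig1", 10, 70, "+"),
                GeneRecord("gB", "contig1", 40, 90, "-")]
        narrow = [GeneRecord("gA", "contig1", 10, 50, "+"),
                  GeneRecord("gB", "contig1", 61, 90, "-")]
        gm_wide = collapse_to_genes(bvm, assign_to_genes(bvm, wide)[0])
        gm_narrow = collapse_to_genes(bvm, assign_to_genes(bvm, narrow)[0])
        gm_narrow = gm_narrow.reindex(index=gm_wide.index,
                                      columns=gm_wide.columns, fill_value=0)
        assert (gm_narrow.values <= gm_wide.values).all()
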