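import numpy as np
import pandas as pd
import pytest

from prewas.alleles import AlleleMatrix


VCF_HEADER = "\n".join([
    "##fileformat=VCFv4.2",
    "##contig=<ID=chr1,length=100000>",
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
])


def write_vcf(path, samples, body_lines, header=VCF_HEADER):
    """Write a small VCF from raw data lines (list of tab-joined strings)."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + \
        "\t".join(samples)
    path.write_text(header + "\n" + cols + "\n" + "\n".join(body_lines) + "\n")
    return path


def make_allele_matrix(rows, samples=None, ref_genome=None, chrom="contig1"):
    """AlleleMatrix from a list of per-site allele-string lists."""
    n = len(rows[0])
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n)]
    if ref_genome is None:
        ref_genome = [next((a for a in r if a != "N"), "A") for r in rows]
    cells = np.empty((len(rows), n), dtype=object)
    for i, r in enumerate(rows):
        cells[i] = r
    sites = pd.DataFrame({
        "key": [str(i + 1) for i in range(len(rows))],
        "chrom": chrom,
        "pos": list(range(1, len(rows) + 1)),
        "ref_genome": ref_genome,
    })
    return AlleleMatrix(samples=list(samples), sites=sites, cells=cells)


def matrix_from_simulation(sim):
    """AlleleMatrix over all simulated sites, genome ref = true root allele."""
    rows = [list(sim.alignment[i]) for i in range(sim.n_sites)]
    refs = [t.root_allele for t in sim.truth]
    return make_allele_matrix(rows, samples=sim.samples, ref_genome=refs)


def random_allele_matrix(rng, n_samples=None, n_sites=None, missing_prob=0.1,
                         indel_prob=0.0):
    """Random allele matrix: 2-4 candidate alleles per site plus N masking."""
    if n_samples is None:
        n_samples = int(rng.integers(4, 13))
    if n_sites is None:
        n_sites = int(rng.integers(20, 61))
    alphabet = ["A", "C", "G", "T"]
    rows, refs = [], []
    for _ in range(n_sites):
        k = int(rng.integers(2, 5))
        pool = list(rng.choice(alphabet, size=k, replace=False))
        if indel_prob and rng.random() < indel_prob:
            pool[-1] = pool[-1] + "G"
        row = [pool[int(rng.integers(k))] for _ in range(n_samples)]
        row = ["N" if rng.random() < missing_prob else a for a in row]
        rows.append(row)
        refs.append(pool[0])
    return make_allele_matrix(rows, ref_genome=refs)


@pytest.fixture
def small_fixture(tmp_path):
    """A deterministic simulated dataset: tree, VCF, GFF, truth files."""
    from prewas import simulate
    phy = simulate.simulate_tree(10, seed=11, height=0.3)
    sim = simulate.evolve_sites(phy, 80, rate=1.0, missing_prob=0.03, seed=12)
    paths = simulate.emit_fixture(sim, tmp_path / "fixture", seed=13)
    return sim, paths
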