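"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as naive loops or exhaustive enumeration and
shares no code path with the package internals it checks.
"""

import itertools
import math

import numpy as np


def er_transition_prob(rate, t, k, same):
    """Closed-form ER transition probability, recomputed independently."""
    e = math.exp(-k * rate * t)
    return (1.0 / k + (k - 1) / k * e) if same else (1.0 - e) / k


def enumeration_site_loglik(itree, tip_states, states, rate, lengths):
    """Site log-likelihood by summing over all internal-node assignments."""
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    internal = [i for i in range(len(itree.labels)) if not itree.is_leaf[i]]
    edges = itree.edges()
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))

        def st(i):
            if i in amap:
                return amap[i]
            return idx[tip_states[itree.labels[i]]]

        p = 1.0 / k  # flat root prior
        for par, ch in edges:
            p *= er_transition_prob(rate, lengths[ch], k,
                                    st(par) == st(ch))
        total += p
    return math.log(total)


def naive_binarize(matrix, refs_by_key):
    """Brute-force re-derivation of the binary variant matrix.

    Loops over sites x alleles x samples; replicates the removal of
    removed sites and of all-zero / all-one rows.  Returns
    {row_key: list of 0/1} in the same (genomic, alphabetical-alt) order.
    """
    out = {}
    n = len(matrix.samples)
    for i, key in enumerate(matrix.site_keys()):
        a = refs_by_key[key]
        if a.removed:
            continue
        row = matrix.row(i)
        alleles = sorted(set(row))
        for allele in alleles:
            if allele == a.reference_allele or allele == "N":
                continue
            vec = []
            for j in range(n):
                vec.append(1 if row[j] == allele else 0)
            if sum(vec) == 0 or sum(vec) == n:
                continue
            out[f"{key}.{allele}"] = vec
    return out


def naive_gene_or(bvm, assignment_pairs):
    """Logical-OR gene matrix via a triple loop over genes/rows/samples."""
    genes = sorted({g for _, g in assignment_pairs})
    out = {}
    for g in genes:
        vec = [0] * len(bvm.samples)
        for row_key, gg in assignment_pairs:
            if gg != g:
                continue
            data = bvm.data.loc[row_key]
            for j in range(len(vec)):
                if int(data.iloc[j]) == 1:
                    vec[j] = 1
        out[g] = vec
    return out


def naive_mean_pairwise_distance(matrix):
    cells = matrix.values()
    n = len(matrix.samples)
    total, pairs = 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            d = 0
            for s in range(matrix.n_sites):
                a, b = cells[s, i], cells[s, j]
                if a != "N" and b != "N" and a != b:
                    d += 1
            total += d
            pairs += 1
    return total / pairs


def naive_multiallelic(matrix):
    n_multi = n_var = 0
    for i in range(matrix.n_sites):
        seen = set()
        for a in matrix.row(i):
            if a != "N":
                seen.add(a)
        if len(seen) >= 2:
            n_var += 1
        if len(seen) > 2:
            n_multi += 1
    return n_multi, n_var
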