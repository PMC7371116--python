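# Methods

## The pre-processing model

`prewas` turns a merged multi-sample VCF of clonal bacterial isolates
into binary feature matrices for association testing. The pipeline is a
composition of pure functions with no hidden state:

1. **Read and normalise the VCF** (`prewas.io`). One record per
   (contig, position); lines pre-split per alternate allele at the same
   position are re-merged with their ALT lists unioned. Genotypes are
   haploid calls; homozygous diploid encodings (`1/1`) collapse to the
   allele, heterozygous ones (`0/1`) are treated as missing with a
   warning, because the data model is clonal — a heterozygous call in a
   haploid organism is evidence of mixed culture or mapping artefact,
   not genotype. Spanning-deletion alleles (`*`) also map to missing.
2. **Allele matrix** (`prewas.alleles`): one row per position, one
   column per sample, cells are allele strings (SNPs and indels alike),
   missing calls rendered as the literal state `"N"`.
3. **Reference allele per site** (`prewas.referencing`), by one of
   three methods — ancestral (ML root state), major (modal allele) or
   genome (VCF REF). Missing data is deliberately a *competing fifth
   allele*: a site whose modal allele or ML root state is `"N"` carries
   no usable polarity and is removed (reasons `major_is_missing`,
   `root_is_missing`). Sites with fewer than two distinct real alleles
   are removed as `invariant`.
4. **Binarization** (`prewas.binarize`): each retained site emits one
   row per distinct non-reference, non-`N` allele; a sample's entry is
   1 iff it carries exactly that allele. Missing and "other alternate
   allele" are both 0. This multi-line representation keeps the minor
   alleles of multiallelic sites as separate, testable features.
5. **Gene matrices** (`prewas.genes`): a variant belongs to *every*
   gene whose 1-based inclusive interval contains its position —
   overlapping genes are common in bacteria and a shared variant can
   have a different predicted functional impact in each gene of the
   pair. Gene rows are the logical OR of their variants; per-impact
   matrices filter contributions by the (variant, gene)-specific SnpEff
   category before collapsing.

## Ancestral reconstruction

For each site, the state space is the set of alleles observed at that
site, including `"N"` when present. The model is an equal-rates (ER)
continuous-time Markov chain — the same default used by `ape::ace` in
R — with transition probability

    P(t)_ij = 1/k + (k-1)/k · exp(-k·r·t)   (i = j)
            = 1/k − 1/k · exp(-k·r·t)       (i ≠ j)

for k states and rate r. The single rate per site is fitted by bounded
one-dimensional maximisation of the tree likelihood (log-rate bracket
[1e-8, 100], tolerance 1e-8), with the likelihood evaluated by
Felsenstein's pruning algorithm under per-node rescaling to avoid
underflow. The root distribution is the scaled marginal likelihood
under a flat root prior; internal-node states (used for convergence
counting) are the argmax of proper marginals computed with an
inside–outside pass. Sites sharing an identical tip-state pattern are
computed once and cached.

Numerical choices:

- zero-length branches are nudged to 1e-9 of tree height; a tree whose
  branches are all zero yields a uniform root distribution (confidence
  1/k) with a warning;
- argmax ties break alphabetically by allele string, so results are
  deterministic and invariant to tip input order;
- the reconstruction is *marginal*, not joint; convergence counts
  therefore use per-node marginal argmax states. Counting is
  edge-based: an allele "arises" on every edge whose parent state
  differs from it and whose child state equals it, and its convergence
  score is arisals − 1, floored at 0.

Treating `"N"` as a real evolving state is unusual but intentional: it
is what makes "the root allele is missing" detectable, which drives the
`root_is_missing` removal rule. It must not be "improved" into an
uninformative-tip convention without changing the removal semantics.

## Reference-method details

- **major**: `"N"` competes; it wins (removing the site) only when
  strictly modal. Ties among real alleles break alphabetically; a tie
  between `"N"` and a real allele resolves to the real allele.
- **ancestral**: root confidence is the maximum scaled marginal
  likelihood. Below the threshold (default 0.875 — the conventional
  cut-off of ≥ 7/8 confidence in the root state) the site falls back
  to the major allele and is flagged `low_confidence_fallback_used`
  rather than removed: the major allele is the accepted alternative
  when ancestral inference is not reliable, and discarding every
  low-confidence site would throw away signal the fallback preserves.
  The threshold is user-configurable.
- **genome** is provided so that method-mismatch reports (genome vs
  major vs ancestral, over retained high-confidence sites, plus the
  low-confidence fraction) can be produced, although it is the least
  interpretable choice for gene-level analyses.

When no tree is supplied in ancestral mode, a neighbour-joining tree is
built from pairwise Hamming distances over sites where both samples are
non-`N` (mismatches / compared sites). NJ is a convenience fallback; an
externally estimated ML tree is preferable and a warning says so. An
outgroup, when given, is used only to root the tree and is pruned before
reconstruction.

## Synthetic data: what it emulates and what it does not

`prewas.simulate` generates the study conditions end to end:

- **Trees**: Yule (pure-birth) topologies with exponential waiting
  times, rescaled so the maximum root-to-tip distance equals the
  requested height (substitutions/site). Deterministic per seed.
- **Sites**: Jukes–Cantor evolution from a uniform random root allele;
  substitutions are a Poisson process along each branch, every event
  recorded, so true root alleles, true node states and true arisal
  counts are known exactly. `multiallelic_boost` multiplies the rate of
  a fixed 10 % subset of sites to enrich for multiallelic sites.
  Missingness is post-hoc masking of tips to `"N"` — the simulation
  truth concerns real alleles only, keeping it independent of the
  fifth-allele convention under test.
- **Serialisation**: VCF v4.2 with merged ALTs and synthetic
  SnpEff-style ANN entries (impact per alt × containing gene, fixed or
  random), GFF3 with overlapping genes, newick, and truth tables.

The generator produces SNPs on a single contig with uniform base
composition, no recombination, no rate heterogeneity beyond the boost,
and missingness independent of phylogeny. Real bacterial data violates
all of these (recombination tracts, GC skew, coverage-driven
missingness, indels). Passing tests therefore demonstrate correctness
of the *encoding, inference and bookkeeping machinery* under the stated
model, not robustness of ancestral inference to model misspecification
on real genomes.

## Problem sizes and defaults

The test-suite oracles run on 100 random fixtures of 4–12 samples ×
20–60 sites (binarization, gene collapsing, statistics — checked
cell-for-cell against naive loops), 200 random trees of ≤ 6 tips and
≤ 4 states (pruning vs exhaustive enumeration, relative error < 1e-9),
and a 25-sample × 400-site reconstruction fixture at root-to-tip
divergence 0.25 substitutions/site with 2 % missingness — low enough
divergence that confident root calls are expected to be correct, which
is what the ≥ 90 % recovery check asserts. `scripts/acceptance.py`
re-runs the same conditions from scratch under the given seed (the
workflow fixture there uses `multiallelic_boost=4` and a random genome
reference so that all three referencing methods genuinely disagree).

## Known limitations

- Marginal (not joint) reconstruction; no rate heterogeneity across
  branches; ER only — no model selection.
- Gene membership is by variant POS only; an indel spanning a gene
  boundary is assigned by its anchor position.
- Heterozygous calls are discarded (as missing) rather than resolved by
  allele depth.
- The mismatch report restricts to sites retained by all compared
  methods with confident roots; fractions are not defined when nothing
  is comparable (reported with an explicit status instead).
- Single-threaded; `--threads` is accepted for interface compatibility
  but currently ignored.
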