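# Methods

## The generative model

The model treats an observed active gene list *G* (a subset of a fixed gene
universe) as the outcome of a two-stage propagation process driven by an
unknown set *C* of active annotation terms:

1. Every gene annotated by a term in *C* is a **core** gene and enters *G*
   independently with probability *p₁*.
2. Activity leaks exactly one step through the interaction network: every
   non-core gene adjacent to a core gene is **peripheral** and enters *G*
   with probability *p₂*. Multi-hop propagation is deliberately excluded —
   the influence of a term is assumed to decay quickly with network
   distance, and one hop keeps the classification unambiguous and cheap.
3. All remaining (**other**) genes enter *G* with a background probability
   *q*, absorbing experimental noise and annotation incompleteness.

The intended regime is *p₁ > p₂ ≫ q*. Parameter validation warns rather
than fails outside that ordering, because the boundary settings below are
legitimate analysis tools.

The log-likelihood of *G* given *C* is the sum of six weighted counts plus
a penalty (see README for the formula). Two conventions matter:

* **Edge counting.** The inactive-core term E₁ counts term→gene annotation
  edges, and the inactive-peripheral term E₂ counts core→peripheral network
  edges, both *with multiplicity*: a gene annotated by k selected terms but
  absent from *G* costs k·log(1−p₁). This is what discourages redundant,
  heavily overlapping term combinations.
* **Boundary probabilities.** 0·log 0 is taken as 0, and a strictly
  positive count multiplying log 0 yields −∞ — an admissibly worst
  solution, not an error. This keeps the search total at boundary
  parameters. With p₁=1, p₂=0, q=0 (and α=0) the finite-likelihood term
  sets are exactly those whose annotation union equals the active list, so
  the model degenerates to maximum-overlap exact cover; with p₁=p₂=1, q=0
  the same holds with the one-hop network closure added to the cover.
  Natural logarithms are used throughout; the arg-max does not depend on
  the base.

### Disjoint classes

An integer-programming formulation of the same objective would allow a
gene to be flagged core and peripheral simultaneously (its class indicator
constraints are one-sided). The verbal model is unambiguous — peripheral
genes are the *non-core* neighbours of core genes — and the double-counted
alternative would award log p₁ + log p₂ to a single active gene. The
classes here are therefore disjoint: core ∪ peripheral ∪ other partitions
the universe for every candidate set. The test suite pins the counts to an
independent double-loop enumeration with exactly this convention.

### The gene universe

The universe is the union of annotated genes and network genes, ordered
lexicographically. Analysis is deliberately *not* restricted to genes
present in both sources: network-only genes can be peripheral and carry
evidence, annotation-only genes can be core. Genes in the input active
list that appear in neither source are dropped with a logged count.

## Search

* **Greedy** (default): score every singleton; start from the best one
  (the empty set is kept as baseline and returned when no singleton beats
  it, which the one-step neighbourhood could otherwise never reach on
  pure-noise inputs); then repeatedly evaluate all single-term additions
  and deletions and apply the strictly best improving move until none
  exists. Strict improvement prevents cycles. Ties are broken
  deterministically: larger objective, then deletions before additions,
  then lexicographically smallest term id — so identical inputs always
  yield identical outputs and traces.
* **Exhaustive** (`method="exhaustive"`, catalogues ≤ 20 terms): enumerate
  all 2^M subsets in Gray-code order (one term toggled per step), used as
  the optimality oracle in tests. Ties prefer smaller sets, then the
  lexicographically smallest sorted id tuple.

Candidate moves are scored by an incremental evaluator that maintains the
six classification counts under single-term pushes/pops in time
proportional to the genes of the term and their neighbourhoods. Its
equivalence with full reclassification is enforced by a 1,000-move
randomised test at 1e-9 absolute tolerance; it is an optimisation, not a
semantic feature.

## Mixed parameter selection

In real data the generating parameters are unknown, and the benchmark
shows the best solving parameters need not equal the generating ones. The
mixed strategy therefore runs a fixed grid — p₁ ∈ {0.8, 0.5},
p₂ ∈ {0.1, 0.05}, q ∈ {0.01, 0.001}, α = 3, i.e. eight combinations, or
the four p₁ × q combinations for the network-free variant, whose objective
cannot depend on p₂ — and ranks the solutions by the one-sided Fisher
exact p-value of each solution's super pseudo term (the union of its
genes) against the active list. Ties keep the grid enumeration order
(p₁, then p₂, then q, each descending), which output files record in their
header.

The network-free variant is the reduction of this model obtained by
scoring on an edgeless network; it is the in-package comparator for
"no network information", not a reimplementation of any external tool.

## Statistics

* `fisher_enrichment_p` computes the hypergeometric upper tail
  P(X ≥ k) by log-sum-exp over log-binomials from a cached log-factorial
  table. The suite verifies 1e-12 relative agreement with exact integer
  summation over *all* configurations with N ≤ 60.
* Bonferroni correction is min(1, m·p) with m the number of terms tested.
* Precision-recall pooling: per-run term scores (corrected hypergeometric
  p-values; terms absent from a method's output imputed 1, so recall is
  well defined) are pooled over all runs into single TP/FP/FN counts at
  each cutoff — one pooled 2×2 table per cutoff rather than an average of
  per-run ratios, which keeps the curve defined when individual runs
  return empty outputs. Precision at zero calls is defined as 1 (no false
  calls). The default cutoff grid is the sorted distinct pooled scores.
* Curve comparison uses the attainable-precision envelope: for each recall
  level r, the best precision among operating points with recall ≥ r.
  One curve weakly dominates another when its envelope is pointwise ≥ over
  a shared recall grid.

## Synthetic data

`make_synthetic_world` generates a random annotation catalogue (term sizes
uniform in a bounded range, genes sampled uniformly without replacement)
and an independent Erdős–Rényi (or preferential-attachment) network over
the same gene pool. Defaults — 500 genes, 150 terms of 5–40 genes, mean
degree 6 — give each planted term a distinct core with natural overlaps
and a one-hop neighbourhood large enough for peripheral activation to
matter, at a scale where a full benchmark runs in seconds.

What the generator deliberately does **not** emulate: the hierarchical
nesting of real ontologies (term sizes are independent, not nested), the
heavy-tailed degree distribution and modularity of curated interactomes
(unless the preferential-attachment model is selected), and any
correlation between term membership and network adjacency. Passing
benchmarks therefore demonstrate correct inference *under the model's own
assumptions* and relative method ordering at desk scale; they do not by
themselves establish performance on real annotation databases, for which
GMT + edge-list inputs of arbitrary size are supported.

`generate_active_genes` classifies the universe by the planted target
terms and activates each gene by an independent Bernoulli draw with its
class probability; empty draws are rejected and redrawn up to 100 times
(the generative story never produces an empty observed list, and rejection
preserves reproducibility from the seed). Calibration is verified at
10,000 draws against 3 binomial standard errors per class.

The benchmark dimensions default to a scaled-down design — 2 annotation
subsamples of 100 terms (after filtering term sizes to 2–500), 10 target
draws of 5 terms each, i.e. 20 runs pooled per method — so the whole study
completes in a few seconds; `SimulationSpec.full_scale()` restores the
10 × 500 × 20 design. Four generating-parameter groups ship as presets:
(0.8, 0.3, 0.001), (0.5, 0.3, 0.001), (0.8, 0.1, 0.001), (0.8, 0.3, 0.01),
all with α = 3. All sampling flows through one seeded NumPy generator.

## Redundancy scoring

ASS(S) = (n choose 2)⁻¹ Σ_{i<j} score(Sᵢ, Sⱼ) averages a pairwise
semantic-similarity score over a term set; combination-based outputs are
expected to score lower (less redundant) than top-n single-term rankings,
which often select ancestor/descendant pairs. The observed ASS is placed
on a background distribution of uniformly resampled same-size term sets
(100,000 repetitions by default, overridable), reported as a midrank
percentile so exact ties — common in degenerate fixtures — behave
sensibly.

The built-in pairwise score is an information-content similarity over the
ontology's is_a DAG: gene counts propagate from descendants to ancestors,
IC(t) = −log(count(t)/total), combined as Lin
(2·IC(mica)/(IC(t₁)+IC(t₂))) or Resnik normalised by the maximum IC. Only
is_a relations are used; part_of and other edge types are ignored. The
score function is pluggable (any callable of two term ids, including a
wrapped precomputed matrix), so externally computed similarity measures
can be substituted without touching the resampling machinery.

## Problem sizes and numerical choices

* Likelihood equivalence tests: 500 random instances, ≤ 8 terms × ≤ 30
  genes, 1e-9 absolute tolerance.
* Greedy optimality: 100 instances of 8 terms / ≤ 40 genes against the
  2⁸ exhaustive maximum; the greedy local optimum is accepted when it
  matches in ≥ 95 of 100 (it can legitimately stop at a local maximum).
* Benchmark checks: 3 independent seeds of the default 20-run study; the
  network-vs-Fisher ordering must hold on ≥ 2 of 3 seeds, and the p₂ = 0
  comparison must stay within 3 standard errors of the seed-to-seed
  spread, with a 0.05 precision floor covering zero-variance grid points.
* Floating-point ties in the search are broken by exact comparison; all
  set serialisation is lexicographic.

## Known limitations

* The incidence matrix is kept as Python sets plus a sparse matrix view;
  catalogues of ~10⁴ terms × ~10⁴ genes are fine, but the greedy search
  cost grows with (terms × mean term size × mean degree) per iteration.
* (p₁, p₂, q) are never estimated from data — by design, the mixed grid
  replaces estimation.
* Only undirected, unweighted networks and one-hop propagation are
  supported.
* The Wang graph-based similarity measure is not implemented; use the
  pluggable score function to inject externally computed matrices.
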