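# netenrich

Network-assisted generative gene-set enrichment analysis.

Classical enrichment tools score each annotation term independently with an
overlap statistic, which tends to return long, redundant lists of nested
terms. `netenrich` instead asks which *combination* of terms best explains
an observed active gene list (for example, the top differentially expressed
genes of a disease/control comparison), and it lets term activity spread one
step through a protein interaction network, so that upstream regulators
whose own expression barely changes can still be identified.

## Model

Given an annotation catalogue (terms → genes), an undirected gene
interaction network, and an active gene list *G*, a candidate term set *C*
partitions the gene universe into

* **core** genes — annotated by at least one term in *C*, observed active
  with probability *p₁*;
* **peripheral** genes — direct network neighbours of core genes, observed
  active with probability *p₂*;
* **other** genes — everything else, active only through noise with
  probability *q* (with *p₁ > p₂ ≫ q*).

The log-likelihood of the observed list under *C* is

```
L(G | C, p₁, p₂, q) = |N₁| log p₁ + |E₁| log(1 − p₁)
                    + |N₂| log p₂ + |E₂| log(1 − p₂)
                    + |O_A| log q + |O_I| log(1 − q) − α |C|
```

where N₁/N₂/O_A are the active core/peripheral/other genes, O_I the
inactive other genes, E₁ the term→inactive-core annotation edges, E₂ the
core→inactive-peripheral network edges (both counted with multiplicity,
which penalises redundant overlapping terms), and α |C| a penalty favouring
small term sets. The maximum-likelihood *C* is found by a greedy one-step
search (best singleton start; repeatedly apply the best single add/delete
move until no move improves). Because the true (p₁, p₂, q) are unknown in
real data, a mixed strategy runs a fixed 2×2×2 parameter grid and ranks the
eight solutions by the Fisher exact p-value of each solution's *super
pseudo term* (the union of its genes) against the active list.

The package also ships the full simulation benchmark (generate active lists
from planted term sets, recover them, pool Bonferroni-corrected
hypergeometric scores into precision-recall curves), an exhaustive search
oracle for tiny catalogues, and an averaged-semantic-similarity (ASS)
redundancy score with a resampled background.

## Worked example

Estimators follow the scikit-learn protocol: parameters in the
constructor, `fit` on the active gene list, results in trailing-underscore
attributes.

```python
import numpy as np
from netenrich import (GENERATING_PRESETS, MixedStrategyEnrichment,
                       make_synthetic_world, generate_active_genes)

world = make_synthetic_world(n_genes=300, n_terms=60, term_size_dist=(4, 20),
                             density_param=5.0, seed=11)
rng = np.random.default_rng(11)
targets = {"T007", "T023", "T041"}            # planted active terms
active = generate_active_genes(targets, world.annotation, world.network,
                               GENERATING_PRESETS["group-i"], rng)
print("active genes:", len(active))

est = MixedStrategyEnrichment(annotation=world.annotation,
                              network=world.network).fit(active)
best = est.best_
print("best parameter combination:",
      (best.params.p1, best.params.p2, best.params.q))
print("selected terms:", sorted(best.term_set))
print("log-likelihood:", round(best.objective.total, 2))
print("combination p-value:", f"{best.fisher_p:.3e}")
```

prints

```
active genes: 62
best parameter combination: (0.8, 0.1, 0.01)
selected terms: ['T007', 'T023', 'T041']
log-likelihood: -103.38
combination p-value: 1.319e-21
```

The 62-gene list was drawn by activating the three planted terms' core
genes with probability 0.8, their network neighbours with 0.3 and all other
genes with 0.001; the top-ranked of the eight grid solutions recovers
exactly the three planted terms, and its gene union is enriched in the
active list at p ≈ 1.3 × 10⁻²¹.

The same workflow is available from the shell:

```bash
netenrich run --gmt annotation.gmt --network edges.tsv \
              --genes active.txt --out results/
netenrich simulate --preset group-i --seed 1 --out sim/
netenrich redundancy --obo go.obo --gmt annotation.gmt \
              --term-set terms.txt --out redundancy.tsv
```

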