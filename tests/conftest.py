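"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities from first principles
(dense double-loop sums over the integer-programming index sets, exact
integer hypergeometric summation) so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from netenrich import (
    ActiveGeneList,
    AnnotationSet,
    GeneNetwork,
    ModelParams,
    build_universe,
)


# ---------------------------------------------------------------------------
# worked toy instance (two overlapping terms, two-edge network)
# ---------------------------------------------------------------------------
@pytest.fixture
def toy_annotation() -> AnnotationSet:
    return AnnotationSet(
        {"T1": ["g1", "g2"], "T2": ["g2", "g3"]},
        {"T1": "first term", "T2": "second term"},
    )


@pytest.fixture
def toy_network() -> GeneNetwork:
    return GeneNetwork([("g3", "g4"), ("g3", "g5")])


@pytest.fixture
def toy_universe(toy_annotation, toy_network):
    return build_universe(toy_annotation, toy_network)


@pytest.fixture
def toy_active(toy_universe) -> ActiveGeneList:
    return ActiveGeneList(["g1", "g4"], toy_universe)


# ---------------------------------------------------------------------------
# random instance generator
# ---------------------------------------------------------------------------
def random_instance(
    rng: np.random.Generator,
    n_terms: int = 6,
    n_genes: int = 20,
    edge_p: float = 0.15,
    active_p: float = 0.3,
    max_term_size: int = 6,
):
    """A random annotation/network/active-list triple plus its universe."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    gene_sets = {}
    for i in range(n_terms):
        size = int(rng.integers(1, max_term_size + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        gene_sets[f"T{i:02d}"] = [genes[j] for j in members]
    annotation = AnnotationSet(gene_sets)
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_p:
                edges.append((genes[i], genes[j]))
    network = GeneNetwork(edges)
    universe = build_universe(annotation, network)
    active_genes = [g for g in universe.gene_ids if rng.random() < active_p]
    if not active_genes:
        active_genes = [universe.gene_ids[0]]
    active = ActiveGeneList(active_genes, universe)
    return annotation, network, active, universe


def random_params(rng: np.random.Generator) -> ModelParams:
    p2 = float(rng.uniform(0.02, 0.4))
    p1 = float(rng.uniform(p2 + 0.05, 0.95))
    q = float(rng.uniform(0.0005, min(0.05, p2)))
    alpha = float(rng.uniform(0.0, 4.0))
    return ModelParams(p1=p1, p2=p2, q=q, alpha=alpha)


# ---------------------------------------------------------------------------
# oracle: dense double-loop classification + term-by-term likelihood
# ---------------------------------------------------------------------------
def dense_arrays(annotation, network, active, universe):
    """Dense A (M x N), B (N x N), g (N) over the universe gene ordering."""
    genes = list(universe.gene_ids)
    index = {g: j for j, g in enumerate(genes)}
    m, n = annotation.n_terms, len(genes)
    A = np.zeros((m, n), dtype=int)
    terms = sorted(annotation.term_ids)
    for i, t in enumerate(terms):
        for g in annotation.genes_of(t):
            A[i, index[g]] = 1
    B = np.zeros((n, n), dtype=int)
    if network is not None:
        for u, v in network.edges():
            B[index[u], index[v]] = 1
            B[index[v], index[u]] = 1
    g_vec = np.array([1 if g in active else 0 for g in genes], dtype=int)
    return terms, A, B, g_vec


def oracle_counts(term_set, terms, A, B, g_vec):
    """Counts (n1, e1, n2, e2, oa, oi) by explicit double loops.

    Follows the integer-program objective with x from term_set, y_j = 1 iff
    some selected term annotates j, and z_j = 1 iff j has a core neighbour
    and is not itself core (disjoint classes).
    """
    m, n = A.shape
    x = np.array([1 if t in term_set else 0 for t in terms], dtype=int)
    y = np.zeros(n, dtype=int)
    for j in range(n):
        for i in range(m):
            if x[i] and A[i, j]:
                y[j] = 1
    z = np.zeros(n, dtype=int)
    for j in range(n):
        if y[j]:
            continue
        for i in range(n):
            if B[i, j] and y[i]:
                z[j] = 1
    n1 = sum(y[j] * g_vec[j] for j in range(n))
    e1 = sum(
        x[i] * A[i, j] * (1 - g_vec[j]) for i in range(m) for j in range(n)
    )
    n2 = sum(z[j] * g_vec[j] for j in range(n))
    e2 = sum(
        y[i] * B[i, j] * (1 - y[j]) * (1 - g_vec[j])
        for i in range(n)
        for j in range(n)
    )
    oa = sum((1 - y[j]) * (1 - z[j]) * g_vec[j] for j in range(n))
    oi = sum((1 - y[j]) * (1 - z[j]) * (1 - g_vec[j]) for j in range(n))
    return n1, e1, n2, e2, oa, oi


def oracle_objective(term_set, terms, A, B, g_vec, params) -> float:
    """Sum the printed likelihood formula term by term over oracle counts."""
    n1, e1, n2, e2, oa, oi = oracle_counts(term_set, terms, A, B, g_vec)

    def xlog(c, p):
        if c == 0:
            return 0.0
        if p == 0.0:
            return -math.inf
        return c * math.log(p)

    return (
        xlog(n1, params.p1)
        + xlog(e1, 1 - params.p1)
        + xlog(n2, params.p2)
        + xlog(e2, 1 - params.p2)
        + xlog(oa, params.q)
        + xlog(oi, 1 - params.q)
        - params.alpha * len(term_set)
    )


# ---------------------------------------------------------------------------
# oracle: exact hypergeometric upper tail via integer arithmetic
# ---------------------------------------------------------------------------
def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    total = math.comb(N, n)
    tail = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    )
    return float(Fraction(tail, total))
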