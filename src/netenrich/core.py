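"""Core domain types and the gene-classification computation.

The model views an experiment as a generative process on a tripartite
structure: annotation terms activate the genes they annotate (*core*
genes), activity leaks one step further to direct interaction-network
neighbours of core genes (*peripheral* genes), and every remaining gene
(*other*) can only be activated by noise.  Everything downstream — the
likelihood, the search, the simulation benchmark — is built on the
partition of the gene universe induced by a candidate term set, computed
here by :func:`classify_genes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "GeneNetwork",
    "GeneUniverse",
    "ActiveGeneList",
    "ModelParams",
    "GeneClassification",
    "build_universe",
    "classify_genes",
]


class AnnotationSet:
    """A binary term-gene incidence relation (the annotation matrix ``A``).

    Parameters
    ----------
    gene_sets
        Mapping from term identifier to an iterable of gene identifiers.
        Every term must annotate at least one gene.
    descriptions
        Optional mapping from term identifier to free-text description.
    """

    def __init__(
        self,
        gene_sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        if not gene_sets:
            raise ValueError("annotation must contain at least one term")
        self._gene_sets: dict[str, frozenset[str]] = {}
        for term, genes in gene_sets.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"term {term!r} annotates no genes")
            if term in self._gene_sets:
                raise ValueError(f"duplicate term id {term!r}")
            self._gene_sets[str(term)] = gs
        self.term_ids: list[str] = list(self._gene_sets)
        all_genes: set[str] = set()
        for gs in self._gene_sets.values():
            all_genes |= gs
        self.gene_ids: list[str] = sorted(all_genes)
        self.descriptions: dict[str, str] = dict(descriptions or {})

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.term_ids)

    def __contains__(self, term: str) -> bool:
        return term in self._gene_sets

    def __repr__(self) -> str:
        return (
            f"AnnotationSet(n_terms={len(self.term_ids)}, "
            f"n_genes={len(self.gene_ids)})"
        )

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def genes_of(self, term: str) -> frozenset[str]:
        try:
            return self._gene_sets[term]
        except KeyError:
            raise KeyError(f"unknown term id {term!r}") from None

    def term_size(self, term: str) -> int:
        return len(self.genes_of(term))

    def gene_sets(self) -> dict[str, frozenset[str]]:
        """Return a copy of the term -> gene-set mapping."""
        return dict(self._gene_sets)

    @property
    def incidence(self) -> sparse.csr_matrix:
        """Binary M x N incidence matrix in ``term_ids`` x ``gene_ids`` order."""
        gene_index = {g: j for j, g in enumerate(self.gene_ids)}
        rows, cols = [], []
        for i, term in enumerate(self.term_ids):
            for g in self._gene_sets[term]:
                rows.append(i)
                cols.append(gene_index[g])
        data = np.ones(len(rows), dtype=np.uint8)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_terms, self.n_genes)
        )

    def restrict_terms(self, terms: Iterable[str]) -> "AnnotationSet":
        """A new AnnotationSet containing only the given terms (order kept)."""
        terms = list(terms)
        return AnnotationSet(
            {t: self.genes_of(t) for t in terms},
            {t: self.descriptions[t] for t in terms if t in self.descriptions},
        )


class GeneNetwork:
    """Simple undirected graph over gene identifiers (adjacency ``B``).

    Self-loops and duplicate (including reversed) edges are rejected here;
    file readers remove them with logged counts before construction.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._adj: dict[str, set[str]] = {}
        self._n_edges = 0
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on gene {u!r}")
            if u in self._adj and v in self._adj[u]:
                raise ValueError(f"duplicate edge {u!r}-{v!r}")
            self._adj.setdefault(u, set()).add(v)
            self._adj.setdefault(v, set()).add(u)
            self._n_edges += 1

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        """Build a simplified network, silently dropping self-loops/duplicates."""
        seen: set[frozenset[str]] = set()
        clean = []
        for u, v in edges:
            if u == v:
                continue
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            clean.append((u, v))
        return cls(clean)

    @property
    def gene_ids(self) -> set[str]:
        return set(self._adj)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) pairs with u < v, lexicographically ordered."""
        out = set()
        for u, nbrs in self._adj.items():
            for v in nbrs:
                out.add((u, v) if u < v else (v, u))
        return sorted(out)

    def neighbors(self, gene: str) -> frozenset[str]:
        return frozenset(self._adj.get(gene, ()))

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def __repr__(self) -> str:
        return f"GeneNetwork(n_genes={len(self._adj)}, n_edges={self._n_edges})"


@dataclass(frozen=True)
class GeneUniverse:
    """The fixed gene universe: union of annotated and network genes.

    Ordering is lexicographic so that every vectorised computation and
    every serialised output is reproducible.
    """

    gene_ids: tuple[str, ...]
    annotated: frozenset[str]
    networked: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene universe is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.annotated or gene in self.networked

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def build_universe(
    annotation: AnnotationSet, network: GeneNetwork | None
) -> GeneUniverse:
    """Union of annotated and network genes with per-gene source flags."""
    annotated = frozenset(annotation.gene_ids)
    networked = frozenset(network.gene_ids) if network is not None else frozenset()
    genes = tuple(sorted(annotated | networked))
    return GeneUniverse(gene_ids=genes, annotated=annotated, networked=networked)


class ActiveGeneList:
    """The observed gene list of interest (vector ``g``), restricted to the universe.

    Genes outside the universe are dropped with a logged warning; the number
    dropped is kept on :attr:`n_dropped`.
    """

    def __init__(self, genes: Iterable[str], universe: GeneUniverse) -> None:
        requested = set(genes)
        kept = {g for g in requested if g in universe}
        dropped = len(requested) - len(kept)
        if dropped:
            logger.warning(
                "%d of %d input genes are outside the gene universe and were dropped",
                dropped,
                len(requested),
            )
        self.gene_ids: frozenset[str] = frozenset(kept)
        self.n_dropped: int = dropped
        self.universe = universe

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids

    def mask(self) -> np.ndarray:
        """Boolean activity vector in universe order."""
        return np.fromiter(
            (g in self.gene_ids for g in self.universe.gene_ids),
            dtype=bool,
            count=len(self.universe),
        )


@dataclass(frozen=True)
class ModelParams:
    """The probability triple (p1, p2, q) and the term-count penalty weight.

    p1 : activation probability of core genes (directly annotated).
    p2 : activation probability of peripheral genes (network neighbours of core).
    q  : background activation probability of all other genes.
    alpha : non-negative weight on the |C| penalty favouring small term sets.

    The model intends p1 > p2 >= q; violating that ordering is legal (the
    boundary special cases rely on it) but triggers a warning.
    """

    p1: float
    p2: float
    q: float
    alpha: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if not (self.p1 > self.p2 >= self.q):
            logger.warning(
                "parameters violate the intended ordering p1 > p2 >= q: "
                "p1=%g, p2=%g, q=%g",
                self.p1,
                self.p2,
                self.q,
            )


@dataclass(frozen=True)
class GeneClassification:
    """The partition of the universe induced by a candidate term set.

    Classes are disjoint: a gene annotated by a selected term is core and is
    never additionally counted as peripheral.  ``e1`` and ``e2`` are *edge*
    counts with multiplicity: an inactive gene annotated by k selected terms
    contributes k to ``e1``; an inactive peripheral gene with k core
    neighbours contributes k to ``e2``.
    """

    core_genes: frozenset[str]
    peripheral_genes: frozenset[str]
    other_genes: frozenset[str]
    n1: int  # active core genes
    e1: int  # term->inactive-core annotation edges
    n2: int  # active peripheral genes
    e2: int  # core->inactive-peripheral network edges
    oa: int  # other active genes
    oi: int  # other inactive genes

    @property
    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self.n1, self.e1, self.n2, self.e2, self.oa, self.oi)


def classify_genes(
    term_set: Iterable[str],
    annotation: AnnotationSet,
    network: GeneNetwork | None,
    active: ActiveGeneList,
    universe: GeneUniverse,
) -> GeneClassification:
    """Partition the universe into core / peripheral / other for a term set.

    core       = union of gene sets of the selected terms
    peripheral = non-core genes with >= 1 network neighbour in the core
    other      = everything else

    Raises ``KeyError`` naming the offending id if a term is unknown.
    """
    terms = sorted(set(term_set))
    core: set[str] = set()
    e1 = 0
    for t in terms:
        genes = annotation.genes_of(t)  # raises KeyError for unknown ids
        core |= genes
        e1 += sum(1 for g in genes if g not in active)

    peripheral: set[str] = set()
    e2 = 0
    if network is not None:
        for g in core:
            peripheral |= network.neighbors(g)
        peripheral -= core
        for g in peripheral:
            if g not in active:
                e2 += len(network.neighbors(g) & core)

    universe_set = set(universe.gene_ids)
    other = universe_set - core - peripheral
    n1 = sum(1 for g in core if g in active)
    n2 = sum(1 for g in peripheral if g in active)
    oa = sum(1 for g in other if g in active)
    oi = len(other) - oa
    return GeneClassification(
        core_genes=frozenset(core),
        peripheral_genes=frozenset(peripheral),
        other_genes=frozenset(other),
        n1=n1,
        e1=e1,
        n2=n2,
        e2=e2,
        oa=oa,
        oi=oi,
    )
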