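"""The log-likelihood objective for a candidate term set.

Given the six classification counts, the log-likelihood of observing the
active gene list ``G`` under a candidate active term set ``C`` is

    L(G | C, p1, p2, q) =  |N1| log p1 + |E1| log(1 - p1)
                         + |N2| log p2 + |E2| log(1 - p2)
                         + |OA| log q  + |OI| log(1 - q)  - alpha |C|

with the convention 0 * log 0 = 0; a strictly positive count multiplying
log 0 yields -inf, which ranks as an admissibly worst solution rather than
an error so that boundary parameter settings (p1 = 1, q = 0, ...) remain
searchable.  Natural logarithms are used throughout; the arg-max is
invariant to the base.

:class:`IncrementalEvaluator` is the work-horse of the search: it keeps the
classification counters up to date under single-term additions and removals
in time proportional to the local neighbourhood touched, instead of
re-scanning the whole universe.  Its equivalence with the direct
:func:`score_term_set` path is enforced by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ActiveGeneList,
    AnnotationSet,
    GeneClassification,
    GeneNetwork,
    GeneUniverse,
    ModelParams,
    classify_genes,
)

__all__ = [
    "LikelihoodValue",
    "log_likelihood",
    "score_term_set",
    "IncrementalEvaluator",
]

_COMPONENT_NAMES = ("n1", "e1", "n2", "e2", "oa", "oi", "penalty")


def _xlog(count: float, p: float) -> float:
    """count * log(p) with 0*log(0) = 0 and positive-count*log(0) = -inf."""
    if count == 0:
        return 0.0
    if p == 0.0:
        return -math.inf
    return count * math.log(p)


@dataclass(frozen=True)
class LikelihoodValue:
    """A log-likelihood broken into its seven additive components."""

    total: float
    components: dict[str, float]

    def __float__(self) -> float:
        return self.total


def log_likelihood(
    classification: GeneClassification, term_count: int, params: ModelParams
) -> LikelihoodValue:
    """Evaluate the objective for pre-computed classification counts."""
    if term_count < 0:
        raise ValueError("term_count must be non-negative")
    n1, e1, n2, e2, oa, oi = classification.counts
    comps = {
        "n1": _xlog(n1, params.p1),
        "e1": _xlog(e1, 1.0 - params.p1),
        "n2": _xlog(n2, params.p2),
        "e2": _xlog(e2, 1.0 - params.p2),
        "oa": _xlog(oa, params.q),
        "oi": _xlog(oi, 1.0 - params.q),
        "penalty": -params.alpha * term_count,
    }
    return LikelihoodValue(total=sum(comps.values()), components=comps)


def score_term_set(
    term_set: Iterable[str],
    annotation: AnnotationSet,
    network: GeneNetwork | None,
    active: ActiveGeneList,
    universe: GeneUniverse,
    params: ModelParams,
    network_free: bool = False,
) -> LikelihoodValue:
    """Classify the universe under ``term_set`` and evaluate the objective.

    With ``network_free=True`` the network is ignored (equivalent to scoring
    on an edgeless copy), so no gene is ever peripheral and the value does
    not depend on ``p2``.
    """
    terms = set(term_set)
    cls = classify_genes(
        terms, annotation, None if network_free else network, active, universe
    )
    return log_likelihood(cls, len(terms), params)


class IncrementalEvaluator:
    """Maintain classification counters under one-term moves.

    The evaluator holds a current term set (initially empty) and exposes
    ``push_term`` / ``pop_term`` to add or remove one term, updating the six
    counts in time proportional to the genes of that term and their network
    neighbourhoods.  ``objective(params)`` evaluates the log-likelihood of
    the current set; ``try_move`` scores a candidate move without changing
    the state observably.
    """

    def __init__(
        self,
        annotation: AnnotationSet,
        network: GeneNetwork | None,
        active: ActiveGeneList,
        universe: GeneUniverse | None = None,
        network_free: bool = False,
    ) -> None:
        from .core import build_universe

        self.annotation = annotation
        self.universe = universe if universe is not None else build_universe(
            annotation, network
        )
        self.network = None if network_free else network
        index = self.universe.index()
        n = len(self.universe)

        # terms sorted lexicographically: the canonical candidate order
        self.term_ids: list[str] = sorted(annotation.term_ids)
        self._term_index = {t: i for i, t in enumerate(self.term_ids)}
        active_set = active.gene_ids
        self._active = np.zeros(n, dtype=bool)
        for g in active_set:
            self._active[index[g]] = True

        self._term_genes: list[np.ndarray] = []
        self._e1_single = np.zeros(len(self.term_ids), dtype=np.int64)
        for i, t in enumerate(self.term_ids):
            genes = annotation.genes_of(t)
            self._term_genes.append(
                np.fromiter((index[g] for g in genes), dtype=np.int64, count=len(genes))
            )
            self._e1_single[i] = sum(1 for g in genes if g not in active_set)

        self._adj: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * n
        if self.network is not None:
            for g in self.network.gene_ids:
                nbrs = self.network.neighbors(g)
                self._adj[index[g]] = np.fromiter(
                    (index[v] for v in nbrs), dtype=np.int64, count=len(nbrs)
                )

        # mutable state
        self._cover = np.zeros(n, dtype=np.int64)  # selected terms covering gene
        self._corenb = np.zeros(n, dtype=np.int64)  # core neighbours of gene
        self._selected: set[int] = set()
        n_active = int(self._active.sum())
        self._n1 = 0
        self._e1 = 0
        self._n2 = 0
        self._e2 = 0
        self._oa = n_active
        self._oi = n - n_active

    # -- state inspection ---------------------------------------------
    @property
    def selected_terms(self) -> frozenset[str]:
        return frozenset(self.term_ids[i] for i in self._selected)

    @property
    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self._n1, self._e1, self._n2, self._e2, self._oa, self._oi)

    def n_active(self) -> int:
        return int(self._active.sum())

    # -- gene flips ----------------------------------------------------
    def _flip_to_core(self, j: int) -> None:
        act = self._active[j]
        if self._corenb[j] > 0:  # was peripheral
            if act:
                self._n2 -= 1
            else:
                self._e2 -= self._corenb[j]
        else:  # was other
            if act:
                self._oa -= 1
            else:
                self._oi -= 1
        if act:
            self._n1 += 1
        cover = self._cover
        corenb = self._corenb
        active = self._active
        for u in self._adj[j]:
            corenb[u] += 1
            if cover[u] == 0:
                if active[u]:
                    if corenb[u] == 1:  # other -> peripheral
                        self._oa -= 1
                        self._n2 += 1
                else:
                    if corenb[u] == 1:
                        self._oi -= 1
                    self._e2 += 1  # one more core->inactive-peripheral edge

    def _flip_from_core(self, j: int) -> None:
        cover = self._cover
        corenb = self._corenb
        active = self._active
        for u in self._adj[j]:
            corenb[u] -= 1
            if cover[u] == 0:
                if active[u]:
                    if corenb[u] == 0:  # peripheral -> other
                        self._n2 -= 1
                        self._oa += 1
                else:
                    self._e2 -= 1
                    if corenb[u] == 0:
                        self._oi += 1
        act = self._active[j]
        if act:
            self._n1 -= 1
        if self._corenb[j] > 0:  # becomes peripheral
            if act:
                self._n2 += 1
            else:
                self._e2 += self._corenb[j]
        else:  # becomes other
            if act:
                self._oa += 1
            else:
                self._oi += 1

    # -- term moves -----------------------------------------------------
    def push_term(self, term_index: int) -> None:
        if term_index in self._selected:
            raise ValueError(f"term {self.term_ids[term_index]!r} already selected")
        self._selected.add(term_index)
        self._e1 += self._e1_single[term_index]
        cover = self._cover
        for j in self._term_genes[term_index]:
            cover[j] += 1
            if cover[j] == 1:
                self._flip_to_core(j)

    def pop_term(self, term_index: int) -> None:
        if term_index not in self._selected:
            raise ValueError(f"term {self.term_ids[term_index]!r} not selected")
        self._selected.remove(term_index)
        self._e1 -= self._e1_single[term_index]
        cover = self._cover
        for j in self._term_genes[term_index]:
            cover[j] -= 1
            if cover[j] == 0:
                self._flip_from_core(j)

    # -- objective -------------------------------------------------------
    @staticmethod
    def log_weights(params: ModelParams) -> tuple[float, ...]:
        def lg(p: float) -> float:
            return math.log(p) if p > 0.0 else -math.inf

        return (
            lg(params.p1),
            lg(1.0 - params.p1),
            lg(params.p2),
            lg(1.0 - params.p2),
            lg(params.q),
            lg(1.0 - params.q),
            params.alpha,
        )

    def objective(self, weights: Sequence[float]) -> float:
        """Objective value of the current set given ``log_weights(params)``."""
        lp1, l1p1, lp2, l1p2, lq, l1q, alpha = weights
        total = 0.0
        for count, w in (
            (self._n1, lp1),
            (self._e1, l1p1),
            (self._n2, lp2),
            (self._e2, l1p2),
            (self._oa, lq),
            (self._oi, l1q),
        ):
            if count:
                total += count * w  # count * (-inf) propagates to -inf
        return total - alpha * len(self._selected)

    def try_move(self, term_index: int, weights: Sequence[float]) -> float:
        """Objective after toggling one term, leaving the state unchanged."""
        if term_index in self._selected:
            self.pop_term(term_index)
            value = self.objective(weights)
            self.push_term(term_index)
        else:
            self.push_term(term_index)
            value = self.objective(weights)
            self.pop_term(term_index)
        return value

    def likelihood_value(self, params: ModelParams) -> LikelihoodValue:
        """Full component breakdown of the current state's objective."""
        cls = GeneClassification(
            core_genes=frozenset(),
            peripheral_genes=frozenset(),
            other_genes=frozenset(),
            n1=self._n1,
            e1=self._e1,
            n2=self._n2,
            e2=self._e2,
            oa=self._oa,
            oi=self._oi,
        )
        return log_likelihood(cls, len(self._selected), params)
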