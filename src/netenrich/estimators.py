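"""Scikit-learn style estimators for generative term-set enrichment.

:class:`GenerativeEnrichment` infers the maximum-likelihood combination of
annotation terms explaining an observed active gene list, using a greedy
one-step search (or exhaustive enumeration on tiny term catalogues).
:class:`MixedStrategyEnrichment` runs the fixed parameter grid used when
the true generating parameters are unknown and ranks the resulting
solutions by the Fisher enrichment p-value of their super pseudo term.

Both follow the scikit-learn estimator protocol: constructor parameters are
stored verbatim, ``fit`` takes the active gene list and sets trailing-
underscore attributes, and ``get_params`` / ``set_params`` / ``clone`` work
as usual.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .core import (
    ActiveGeneList,
    AnnotationSet,
    GeneNetwork,
    GeneUniverse,
    ModelParams,
    build_universe,
    classify_genes,
)
from .likelihood import IncrementalEvaluator, log_likelihood
from .search import EnrichmentSolution, SearchTrace
from .stats import ContingencyCounts, fisher_enrichment_p

__all__ = ["GenerativeEnrichment", "MixedStrategyEnrichment"]

# Candidate parameter grid of the mixed selection strategy.
MIXED_GRID_P1 = (0.8, 0.5)
MIXED_GRID_P2 = (0.1, 0.05)
MIXED_GRID_Q = (0.01, 0.001)
MIXED_ALPHA = 3.0


def _as_active(
    X: ActiveGeneList | Iterable[str], universe: GeneUniverse
) -> ActiveGeneList:
    if isinstance(X, ActiveGeneList):
        if X.universe is universe:
            return X
        return ActiveGeneList(X.gene_ids, universe)
    return ActiveGeneList(X, universe)


def _gray_code_moves(m: int):
    """Term index toggled at each step of the binary reflected Gray code.

    Yields m ... such that toggling the yielded index visits every subset of
    {0..m-1} exactly once, starting from the empty set.
    """
    for step in range(1, 2**m):
        yield (step & -step).bit_length() - 1


class GenerativeEnrichment(BaseEstimator):
    """Infer the active term combination behind a gene list of interest.

    The model assumes the observed active gene list was generated by an
    unknown set of active annotation terms: genes annotated by an active
    term (core genes) are observed with probability ``p1``, direct network
    neighbours of core genes (peripheral genes) with probability ``p2``,
    and every other gene with a small background probability ``q``.  Fitting
    maximises the resulting log-likelihood, penalised by ``alpha`` per
    selected term, over term subsets.

    Parameters
    ----------
    annotation
        The term-gene annotation catalogue.
    network
        Undirected gene interaction network; ``None`` means no network.
    p1, p2, q
        Activation probabilities of core, peripheral and other genes.
    alpha
        Non-negative per-term penalty weight.
    network_free
        If True, score on an edgeless copy of the network (no peripheral
        class; the objective is then independent of ``p2``).
    method
        ``"greedy"`` (default) or ``"exhaustive"`` (all subsets; catalogue
        limited to 20 terms).

    Attributes
    ----------
    terms_ : frozenset of selected term ids
    objective_ : LikelihoodValue of the selected set
    trace_ : SearchTrace (greedy only)
    pseudo_term_genes_ : union of genes annotated by the selected terms
    fisher_p_ : Fisher enrichment p of the pseudo term vs the active list
    solution_ : the full EnrichmentSolution record
    universe_, classification_, n_dropped_genes_
    """

    def __init__(
        self,
        annotation: AnnotationSet | None = None,
        network: GeneNetwork | None = None,
        p1: float = 0.8,
        p2: float = 0.1,
        q: float = 0.01,
        alpha: float = 3.0,
        network_free: bool = False,
        method: str = "greedy",
    ) -> None:
        self.annotation = annotation
        self.network = network
        self.p1 = p1
        self.p2 = p2
        self.q = q
        self.alpha = alpha
        self.network_free = network_free
        self.method = method

    # ------------------------------------------------------------------
    def _validate(self) -> ModelParams:
        if self.annotation is None or len(self.annotation) == 0:
            raise ValueError("a non-empty annotation is required")
        if self.method not in ("greedy", "exhaustive"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "exhaustive" and self.annotation.n_terms > 20:
            raise ValueError(
                f"exhaustive search supports at most 20 terms, got "
                f"{self.annotation.n_terms}; use method='greedy'"
            )
        return ModelParams(p1=self.p1, p2=self.p2, q=self.q, alpha=self.alpha)

    def fit(self, X: ActiveGeneList | Iterable[str], y=None) -> "GenerativeEnrichment":
        """Run the search for the active gene list ``X`` (iterable of gene ids)."""
        params = self._validate()
        universe = build_universe(self.annotation, self.network)
        active = _as_active(X, universe)
        if len(active) == 0:
            raise ValueError(
                "active gene list is empty after intersection with the universe"
            )
        ev = IncrementalEvaluator(
            self.annotation,
            self.network,
            active,
            universe=universe,
            network_free=self.network_free,
        )
        weights = ev.log_weights(params)
        if self.method == "greedy":
            terms, trace = self._greedy(ev, weights)
        else:
            terms, trace = self._exhaustive(ev, weights)

        term_set = frozenset(terms)
        cls = classify_genes(
            term_set,
            self.annotation,
            None if self.network_free else self.network,
            active,
            universe,
        )
        objective = log_likelihood(cls, len(term_set), params)
        pseudo = frozenset().union(
            *(self.annotation.genes_of(t) for t in term_set)
        ) if term_set else frozenset()
        fisher_p = fisher_enrichment_p(
            ContingencyCounts(
                k=len(pseudo & active.gene_ids),
                K=len(pseudo),
                n=len(active),
                N=len(universe),
            )
        )
        term_pvalues = {
            t: fisher_enrichment_p(
                ContingencyCounts(
                    k=len(self.annotation.genes_of(t) & active.gene_ids),
                    K=len(self.annotation.genes_of(t)),
                    n=len(active),
                    N=len(universe),
                )
            )
            for t in term_set
        }
        self.universe_ = universe
        self.active_ = active
        self.n_dropped_genes_ = active.n_dropped
        self.terms_ = term_set
        self.objective_ = objective
        self.trace_ = trace
        self.classification_ = cls
        self.pseudo_term_genes_ = pseudo
        self.fisher_p_ = fisher_p
        self.solution_ = EnrichmentSolution(
            term_set=term_set,
            objective=objective,
            params=params,
            pseudo_term_genes=pseudo,
            fisher_p=fisher_p,
            trace=trace,
            term_pvalues=term_pvalues,
            variant="network_free" if self.network_free else "network",
        )
        return self

    # ------------------------------------------------------------------
    def _greedy(
        self, ev: IncrementalEvaluator, weights: Sequence[float]
    ) -> tuple[set[str], SearchTrace]:
        """Best-singleton start, then strictly improving one-step moves.

        Ties among equally good moves are broken deterministically:
        deletions before additions, then lexicographically smallest term id
        (candidates are scanned in that order and only a strictly better
        objective displaces the incumbent).
        """
        term_ids = ev.term_ids  # lexicographically sorted
        m = len(term_ids)
        empty_value = ev.objective(weights)

        best_single, best_value = None, -math.inf
        for i in range(m):
            v = ev.try_move(i, weights)
            if v > best_value:
                best_single, best_value = i, v
        if best_single is None or not best_value > empty_value:
            trace = SearchTrace(
                initial_term=None,
                initial_value=empty_value,
                moves=(),
                termination="empty_set_optimal",
            )
            return set(), trace

        ev.push_term(best_single)
        current = best_value
        selected = {best_single}
        moves: list[tuple[str, str, float]] = []
        while True:
            best_move, best_obj = None, current
            # deletions first, then additions, each in lexicographic order
            for i in sorted(selected):
                v = ev.try_move(i, weights)
                if v > best_obj:
                    best_move, best_obj = ("delete", i), v
            for i in range(m):
                if i in selected:
                    continue
                v = ev.try_move(i, weights)
                if v > best_obj:
                    best_move, best_obj = ("add", i), v
            if best_move is None:
                break
            kind, i = best_move
            if kind == "add":
                ev.push_term(i)
                selected.add(i)
            else:
                ev.pop_term(i)
                selected.remove(i)
            current = best_obj
            moves.append((kind, term_ids[i], current))
        trace = SearchTrace(
            initial_term=term_ids[best_single],
            initial_value=best_value,
            moves=tuple(moves),
            termination="no_improving_move",
        )
        return {term_ids[i] for i in selected}, trace

    def _exhaustive(
        self, ev: IncrementalEvaluator, weights: Sequence[float]
    ) -> tuple[set[str], None]:
        """Enumerate all subsets via Gray code (one term toggled per step).

        Ties are broken by smaller set size, then by the lexicographically
        smallest sorted tuple of term ids.
        """
        term_ids = ev.term_ids
        m = len(term_ids)
        current: set[int] = set()

        def key(sel: set[int]) -> tuple:
            return (len(sel), tuple(sorted(term_ids[i] for i in sel)))

        best_sel = set()
        best_val = ev.objective(weights)
        best_key = key(best_sel)
        for i in _gray_code_moves(m):
            if i in current:
                ev.pop_term(i)
                current.remove(i)
            else:
                ev.push_term(i)
                current.add(i)
            v = ev.objective(weights)
            if v > best_val or (v == best_val and key(current) < best_key):
                best_sel = set(current)
                best_val = v
                best_key = key(best_sel)
        for i in list(current):  # restore the evaluator
            ev.pop_term(i)
        return {term_ids[i] for i in best_sel}, None


class MixedStrategyEnrichment(BaseEstimator):
    """Run the fixed candidate parameter grid and rank solutions.

    With a network, all eight combinations of p1 in {0.8, 0.5}, p2 in
    {0.1, 0.05}, q in {0.01, 0.001} (alpha = 3) are searched; without a
    network (``network_free=True``) the objective does not depend on p2, so
    the four p1 x q combinations are searched.  Each solution's genes are
    unioned into a super pseudo term, whose Fisher enrichment p-value
    against the active list ranks the solutions (ascending; ties keep the
    grid enumeration order, p1 then p2 then q, each descending).

    Attributes
    ----------
    solutions_ : list of EnrichmentSolution, sorted by combination p-value
    best_ : the top-ranked solution
    """

    def __init__(
        self,
        annotation: AnnotationSet | None = None,
        network: GeneNetwork | None = None,
        network_free: bool = False,
        p1_values: Sequence[float] = MIXED_GRID_P1,
        p2_values: Sequence[float] = MIXED_GRID_P2,
        q_values: Sequence[float] = MIXED_GRID_Q,
        alpha: float = MIXED_ALPHA,
    ) -> None:
        self.annotation = annotation
        self.network = network
        self.network_free = network_free
        self.p1_values = p1_values
        self.p2_values = p2_values
        self.q_values = q_values
        self.alpha = alpha

    def grid(self) -> list[tuple[float, float, float]]:
        """(p1, p2, q) combinations in enumeration order."""
        if self.network_free:
            # p2 is irrelevant without a network; fix it at the grid's first value
            return [
                (p1, self.p2_values[0], q)
                for p1, q in itertools.product(self.p1_values, self.q_values)
            ]
        return list(
            itertools.product(self.p1_values, self.p2_values, self.q_values)
        )

    def fit(self, X: ActiveGeneList | Iterable[str], y=None) -> "MixedStrategyEnrichment":
        solutions: list[EnrichmentSolution] = []
        for idx, (p1, p2, q) in enumerate(self.grid()):
            est = GenerativeEnrichment(
                annotation=self.annotation,
                network=self.network,
                p1=p1,
                p2=p2,
                q=q,
                alpha=self.alpha,
                network_free=self.network_free,
                method="greedy",
            )
            est.fit(X)
            sol = est.solution_
            solutions.append(
                EnrichmentSolution(
                    term_set=sol.term_set,
                    objective=sol.objective,
                    params=sol.params,
                    pseudo_term_genes=sol.pseudo_term_genes,
                    fisher_p=sol.fisher_p,
                    trace=sol.trace,
                    term_pvalues=sol.term_pvalues,
                    variant=sol.variant,
                    grid_index=idx,
                )
            )
        solutions.sort(key=lambda s: (s.fisher_p, s.grid_index))
        self.solutions_ = solutions
        self.best_ = solutions[0]
        return self
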