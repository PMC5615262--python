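"""Term-set search results and thin functional wrappers.

The search algorithms live on the estimator classes in
:mod:`netenrich.estimators`; the functions here are convenience wrappers
for scripted use.  :class:`EnrichmentSolution` is the common result record:
the selected term set, its log-likelihood, the super pseudo term (union of
all genes annotated by the set) and its Fisher enrichment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .core import ActiveGeneList, AnnotationSet, GeneNetwork, ModelParams
from .likelihood import LikelihoodValue

__all__ = [
    "SearchTrace",
    "EnrichmentSolution",
    "greedy_search",
    "exhaustive_search",
    "mixed_strategy",
]

Variant = Literal["network", "network_free"]


@dataclass(frozen=True)
class SearchTrace:
    """Record of a greedy run: initial singleton, moves, termination reason.

    Objective values are strictly increasing along the trace.
    """

    initial_term: str | None
    initial_value: float
    moves: tuple[tuple[str, str, float], ...]  # (kind 'add'/'delete', term, value)
    termination: str

    @property
    def values(self) -> list[float]:
        return [self.initial_value] + [v for _, _, v in self.moves]


@dataclass(frozen=True)
class EnrichmentSolution:
    """A term set with its objective, pseudo-term union and enrichment p."""

    term_set: frozenset[str]
    objective: LikelihoodValue
    params: ModelParams
    pseudo_term_genes: frozenset[str]
    fisher_p: float
    trace: SearchTrace | None = None
    term_pvalues: dict[str, float] = field(default_factory=dict)
    variant: str = "network"
    grid_index: int | None = None

    def sorted_terms(self) -> list[str]:
        return sorted(self.term_set)


def greedy_search(
    annotation: AnnotationSet,
    network: GeneNetwork | None,
    active: ActiveGeneList | Iterable[str],
    params: ModelParams,
    variant: Variant = "network",
) -> EnrichmentSolution:
    """Greedy one-step maximum-likelihood search (see GenerativeEnrichment)."""
    from .estimators import GenerativeEnrichment

    est = GenerativeEnrichment(
        annotation=annotation,
        network=network,
        p1=params.p1,
        p2=params.p2,
        q=params.q,
        alpha=params.alpha,
        network_free=(variant == "network_free"),
        method="greedy",
    )
    est.fit(active)
    return est.solution_


def exhaustive_search(
    annotation: AnnotationSet,
    network: GeneNetwork | None,
    active: ActiveGeneList | Iterable[str],
    params: ModelParams,
    variant: Variant = "network",
) -> EnrichmentSolution:
    """Brute-force global maximiser over all 2^M term subsets (M <= 20)."""
    from .estimators import GenerativeEnrichment

    est = GenerativeEnrichment(
        annotation=annotation,
        network=network,
        p1=params.p1,
        p2=params.p2,
        q=params.q,
        alpha=params.alpha,
        network_free=(variant == "network_free"),
        method="exhaustive",
    )
    est.fit(active)
    return est.solution_


def mixed_strategy(
    annotation: AnnotationSet,
    network: GeneNetwork | None,
    active: ActiveGeneList | Iterable[str],
    variant: Variant = "network",
) -> list[EnrichmentSolution]:
    """Run the fixed parameter grid and rank solutions by combination p-value.

    The network variant runs all eight combinations of p1 in {0.8, 0.5},
    p2 in {0.1, 0.05}, q in {0.01, 0.001} (alpha = 3); the network-free
    variant runs the four p1 x q combinations, since without a network the
    objective does not depend on p2.
    """
    from .estimators import MixedStrategyEnrichment

    est = MixedStrategyEnrichment(
        annotation=annotation,
        network=network,
        network_free=(variant == "network_free"),
    )
    est.fit(active)
    return est.solutions_
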