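"""Term-set redundancy via averaged semantic similarity.

A term set identified by a combination-based method should be less
redundant than the top-n single-term ranking, which tends to pick nested
ancestor/descendant terms.  Redundancy is quantified by the averaged
semantic similarity score

    ASS(S) = (n choose 2)^-1  sum_{i < j} score(S_i, S_j)

compared against a background distribution obtained by resampling random
term sets of the same size (100,000 draws by default).

The pairwise score is pluggable (any callable of two term ids).  The
built-in scorer is an information-content similarity over the ontology
is_a DAG: IC(t) = -log(annotated(t) / total), with gene counts propagated
from descendants to ancestors, combined as Lin similarity
2 IC(mica) / (IC(t1) + IC(t2)) or as Resnik similarity normalised by the
maximum IC.  Externally computed similarity matrices can be injected via
``matrix_score_fn`` for workflows that rely on other measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from graphlib import TopologicalSorter
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core import AnnotationSet

__all__ = [
    "OntologyDag",
    "RedundancyReport",
    "InformationContentSimilarity",
    "pairwise_similarity",
    "ass",
    "background_distribution",
    "compare_method_redundancy",
    "matrix_score_fn",
]

ScoreFn = Callable[[str, str], float]


class OntologyDag:
    """A rooted is_a hierarchy: term -> tuple of parents (acyclic)."""

    def __init__(
        self,
        parents: Mapping[str, Sequence[str]],
        namespaces: Mapping[str, str] | None = None,
    ) -> None:
        self._parents: dict[str, tuple[str, ...]] = {
            t: tuple(ps) for t, ps in parents.items()
        }
        for t, ps in self._parents.items():
            for p in ps:
                if p not in self._parents:
                    raise ValueError(f"parent {p!r} of {t!r} is not a term in the DAG")
        # raises CycleError on cycles
        self._topo_order: list[str] = list(
            TopologicalSorter({t: set(ps) for t, ps in self._parents.items()}).static_order()
        )
        self.namespaces: dict[str, str] = dict(namespaces or {})

    @classmethod
    def from_obo(cls, path) -> "OntologyDag":
        """Read an OBO file, keeping only is_a relations (via obonet)."""
        import obonet

        graph = obonet.read_obo(path)
        parents: dict[str, list[str]] = {t: [] for t in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].append(parent)
        namespaces = {
            t: data["namespace"]
            for t, data in graph.nodes(data=True)
            if "namespace" in data
        }
        return cls(parents, namespaces)

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def term_ids(self) -> list[str]:
        return list(self._parents)

    def parents(self, term: str) -> tuple[str, ...]:
        try:
            return self._parents[term]
        except KeyError:
            raise KeyError(f"term {term!r} not in the ontology DAG") from None

    def roots(self) -> list[str]:
        return [t for t, ps in self._parents.items() if not ps]

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable via is_a (optionally including the term itself)."""
        self.parents(term)  # existence check
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for p in self._parents[t]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        if include_self:
            seen.add(term)
        return frozenset(seen)

    def topological_order(self) -> list[str]:
        """Terms ordered with every parent before its children."""
        return list(self._topo_order)


class InformationContentSimilarity:
    """Annotation-frequency information content over an ontology DAG.

    Gene counts are propagated upward: a gene annotated to a term counts
    for all of that term's ancestors.  IC(t) = -log(count(t) / total) where
    ``total`` is the number of distinct annotated genes (so any term
    covering every gene — typically the root — has IC 0).

    method "lin": 2 IC(mica) / (IC(t1) + IC(t2)), 0 when both ICs are 0.
    method "resnik_normalized": IC(mica) / max IC over scorable terms.
    """

    def __init__(
        self,
        dag: OntologyDag,
        annotation: AnnotationSet,
        method: str = "lin",
    ) -> None:
        if method not in ("lin", "resnik_normalized"):
            raise ValueError(f"unknown similarity method {method!r}")
        self.dag = dag
        self.method = method
        # propagate gene sets from terms to all ancestors
        propagated: dict[str, set[str]] = {t: set() for t in dag.term_ids}
        for t in annotation.term_ids:
            if t not in propagated:
                continue
            genes = annotation.genes_of(t)
            for anc in dag.ancestors(t, include_self=True):
                propagated[anc] |= genes
        all_genes: set[str] = set()
        for gs in propagated.values():
            all_genes |= gs
        self._total = len(all_genes)
        self._ic: dict[str, float] = {}
        for t, gs in propagated.items():
            if gs:
                self._ic[t] = -math.log(len(gs) / self._total)
        self._max_ic = max(self._ic.values(), default=0.0)
        self._anc_cache: dict[str, frozenset[str]] = {}

    def ic(self, term: str) -> float:
        """Information content; raises if no gene reaches the term."""
        if term not in self.dag:
            raise KeyError(f"term {term!r} not in the ontology DAG")
        try:
            return self._ic[term]
        except KeyError:
            raise ValueError(
                f"information content of {term!r} is undefined: no annotated "
                "gene at the term or its descendants"
            ) from None

    def _ancestors(self, term: str) -> frozenset[str]:
        if term not in self._anc_cache:
            self._anc_cache[term] = self.dag.ancestors(term, include_self=True)
        return self._anc_cache[term]

    def mica_ic(self, t1: str, t2: str) -> float:
        """IC of the most informative common ancestor (0 if none is scorable)."""
        common = self._ancestors(t1) & self._ancestors(t2)
        return max((self._ic.get(t, 0.0) for t in common), default=0.0)

    def __call__(self, t1: str, t2: str) -> float:
        ic1, ic2 = self.ic(t1), self.ic(t2)
        shared = self.mica_ic(t1, t2)
        if self.method == "lin":
            if ic1 + ic2 == 0.0:
                return 0.0
            return 2.0 * shared / (ic1 + ic2)
        if self._max_ic == 0.0:
            return 0.0
        return shared / self._max_ic


def pairwise_similarity(
    t1: str,
    t2: str,
    dag: OntologyDag,
    annotation: AnnotationSet,
    method: str = "lin",
) -> float:
    """One-off pairwise similarity (builds the IC table; prefer the class
    for repeated scoring)."""
    return InformationContentSimilarity(dag, annotation, method)(t1, t2)


def matrix_score_fn(matrix: Mapping[tuple[str, str], float]) -> ScoreFn:
    """Wrap a precomputed symmetric (t1, t2) -> score mapping as a score_fn."""

    def score(t1: str, t2: str) -> float:
        if (t1, t2) in matrix:
            return float(matrix[(t1, t2)])
        return float(matrix[(t2, t1)])

    return score


def ass(term_set: Iterable[str], score_fn: ScoreFn) -> float:
    """Averaged semantic similarity: mean pairwise score over the set."""
    terms = sorted(set(term_set))
    n = len(terms)
    if n < 2:
        raise ValueError(f"averaged semantic similarity needs >= 2 terms, got {n}")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += score_fn(terms[i], terms[j])
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class RedundancyReport:
    """Observed ASS of a term set against a resampled background."""

    observed_ass: float | None
    background_samples: np.ndarray
    percentile: float | None  # midrank percentile of observed among background
    set_size: int

    @property
    def background_mean(self) -> float:
        return float(np.mean(self.background_samples))


def _midrank_percentile(observed: float, samples: np.ndarray) -> float:
    less = float(np.sum(samples < observed))
    equal = float(np.sum(samples == observed))
    return 100.0 * (less + 0.5 * equal) / len(samples)


def background_distribution(
    n: int,
    annotation: AnnotationSet,
    dag: OntologyDag | None,
    score_fn: ScoreFn,
    repetitions: int = 100_000,
    rng: np.random.Generator | None = None,
    observed: float | None = None,
) -> RedundancyReport:
    """ASS of ``repetitions`` uniformly resampled size-n term sets.

    ``dag`` is accepted for interface symmetry but sampling draws from the
    annotation's term catalogue; the score_fn carries the ontology.  The
    report includes the midrank percentile of ``observed`` (if supplied)
    among the background samples.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    terms = sorted(annotation.term_ids)
    if len(terms) < n:
        raise ValueError(
            f"annotation has only {len(terms)} terms; cannot sample sets of size {n}"
        )
    if rng is None:
        rng = np.random.default_rng()
    samples = np.empty(repetitions)
    for r in range(repetitions):
        idx = rng.choice(len(terms), size=n, replace=False)
        samples[r] = ass((terms[i] for i in idx), score_fn)
    percentile = (
        _midrank_percentile(observed, samples) if observed is not None else None
    )
    return RedundancyReport(
        observed_ass=observed,
        background_samples=samples,
        percentile=percentile,
        set_size=n,
    )


def compare_method_redundancy(
    term_sets: Mapping[str, Iterable[str]],
    annotation: AnnotationSet,
    dag: OntologyDag | None,
    score_fn: ScoreFn,
    repetitions: int = 100_000,
    rng: np.random.Generator | None = None,
) -> dict[str, RedundancyReport]:
    """Score each method's term set against a shared same-size background.

    Methods whose sets have equal size share one background sample, so
    their percentiles are directly comparable.
    """
    if rng is None:
        rng = np.random.default_rng()
    sets = {m: sorted(set(ts)) for m, ts in term_sets.items()}
    for m, ts in sets.items():
        if len(ts) < 2:
            raise ValueError(f"term set for {m!r} has fewer than 2 terms")
    backgrounds: dict[int, np.ndarray] = {}
    reports: dict[str, RedundancyReport] = {}
    for m, ts in sets.items():
        n = len(ts)
        if n not in backgrounds:
            backgrounds[n] = background_distribution(
                n, annotation, dag, score_fn, repetitions, rng
            ).background_samples
        observed = ass(ts, score_fn)
        samples = backgrounds[n]
        reports[m] = RedundancyReport(
            observed_ass=observed,
            background_samples=samples,
            percentile=_midrank_percentile(observed, samples),
            set_size=n,
        )
    return reports
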