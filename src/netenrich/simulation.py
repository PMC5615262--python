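"""Synthetic worlds and the simulation benchmark.

The benchmark follows the generative model exactly: sample an annotation
subset, pick a target set of "truly active" terms, draw an active gene list
by activating core genes with probability p1, peripheral genes with p2 and
all other genes with q, then ask each method to recover the target terms.
Per-term significance scores (Bonferroni-corrected hypergeometric p-values;
terms absent from a method's output scored 1) are pooled over all runs into
a single precision-recall curve per method.

Because no external annotation or interaction database is bundled,
:func:`make_synthetic_world` generates a random annotation catalogue and a
random simple network over a shared gene pool; the default study dimensions
are a scaled-down version of the full design (which remains configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import (
    ActiveGeneList,
    AnnotationSet,
    GeneNetwork,
    ModelParams,
    build_universe,
    classify_genes,
)
from .search import EnrichmentSolution, greedy_search
from .stats import ContingencyCounts, PRCurve, bonferroni, fisher_enrichment_p, pooled_pr_curve

__all__ = [
    "GENERATING_PRESETS",
    "SimulationSpec",
    "SyntheticWorld",
    "SimulationResult",
    "make_synthetic_world",
    "subsample_annotation",
    "generate_active_genes",
    "run_simulation_study",
]

# The four generating-parameter groups of the benchmark design.
GENERATING_PRESETS: dict[str, ModelParams] = {
    "group-i": ModelParams(p1=0.8, p2=0.3, q=0.001, alpha=3.0),
    "group-ii": ModelParams(p1=0.5, p2=0.3, q=0.001, alpha=3.0),
    "group-iii": ModelParams(p1=0.8, p2=0.1, q=0.001, alpha=3.0),
    "group-iv": ModelParams(p1=0.8, p2=0.3, q=0.01, alpha=3.0),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Dimensions of a simulation study.

    Defaults are the desk-scale configuration (2 annotation sets of 100
    terms, 10 target draws each); :meth:`full_scale` gives the original
    10 x 500-term x 20-target design.
    """

    generating_params: ModelParams
    n_annotation_sets: int = 2
    terms_per_set: int = 100
    term_size_range: tuple[int, int] = (2, 500)
    targets_per_set: int = 10
    active_terms_per_target: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid term size range {self.term_size_range}")
        for name in (
            "n_annotation_sets",
            "terms_per_set",
            "targets_per_set",
            "active_terms_per_target",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def full_scale(
        cls, generating_params: ModelParams, rng_seed: int = 0
    ) -> "SimulationSpec":
        return cls(
            generating_params=generating_params,
            n_annotation_sets=10,
            terms_per_set=500,
            targets_per_set=20,
            rng_seed=rng_seed,
        )


@dataclass(frozen=True)
class SyntheticWorld:
    """A random annotation catalogue plus interaction network (seeded)."""

    annotation: AnnotationSet
    network: GeneNetwork
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_synthetic_world(
    n_genes: int = 500,
    n_terms: int = 150,
    term_size_dist: tuple[int, int] = (5, 40),
    network_model: Literal["erdos_renyi", "preferential_attachment"] = "erdos_renyi",
    density_param: float = 6.0,
    seed: int = 0,
) -> SyntheticWorld:
    """Random annotation and network over a shared gene pool.

    Each term draws its size uniformly from ``term_size_dist`` (inclusive)
    and samples that many genes uniformly without replacement.  The network
    is an Erdos-Renyi graph with expected mean degree ``density_param``, or
    a preferential-attachment graph with ``int(density_param)`` edges per
    new node.  Fully reproducible from the seed.
    """
    if n_terms < 1:
        raise ValueError("annotation must contain at least one term")
    lo, hi = term_size_dist
    if hi > n_genes:
        raise ValueError(f"term size bound {hi} exceeds gene count {n_genes}")
    rng = np.random.default_rng(seed)
    width = max(len(str(n_genes - 1)), 4)
    genes = np.array([f"g{i:0{width}d}" for i in range(n_genes)])
    twidth = max(len(str(n_terms - 1)), 3)
    gene_sets = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        gene_sets[f"T{i:0{twidth}d}"] = [genes[j] for j in sorted(members)]

    graph_seed = int(rng.integers(0, 2**31 - 1))
    if network_model == "erdos_renyi":
        p = min(1.0, density_param / max(n_genes - 1, 1))
        graph = nx.gnp_random_graph(n_genes, p, seed=graph_seed)
    elif network_model == "preferential_attachment":
        m = max(1, int(density_param))
        graph = nx.barabasi_albert_graph(n_genes, m, seed=graph_seed)
    else:
        raise ValueError(f"unknown network model {network_model!r}")
    network = GeneNetwork.from_edges(
        (genes[u], genes[v]) for u, v in graph.edges()
    )
    return SyntheticWorld(
        annotation=AnnotationSet(gene_sets),
        network=network,
        params={
            "n_genes": n_genes,
            "n_terms": n_terms,
            "term_size_dist": term_size_dist,
            "network_model": network_model,
            "density_param": density_param,
        },
        seed=seed,
    )


def subsample_annotation(
    full: AnnotationSet,
    size_range: tuple[int, int],
    n_terms: int,
    rng: np.random.Generator,
) -> AnnotationSet:
    """Filter terms to the size range, sample ``n_terms`` without replacement.

    The sampled catalogue's gene list is restricted to the genes covered by
    the sample (AnnotationSet derives its gene list from its terms).
    """
    lo, hi = size_range
    eligible = [t for t in full.term_ids if lo <= full.term_size(t) <= hi]
    if len(eligible) < n_terms:
        raise ValueError(
            f"only {len(eligible)} terms fall in the size range "
            f"{size_range}; {n_terms} requested"
        )
    chosen = rng.choice(len(eligible), size=n_terms, replace=False)
    return full.restrict_terms(eligible[i] for i in sorted(chosen))


def generate_active_genes(
    target_terms: Iterable[str],
    annotation: AnnotationSet,
    network: GeneNetwork | None,
    params: ModelParams,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> ActiveGeneList:
    """Draw an active gene list under the generative model.

    The universe is classified by the target term set; each gene is then
    independently activated with probability p1 (core), p2 (peripheral) or
    q (other).  Empty draws are rejected and redrawn up to ``max_redraws``
    times.
    """
    universe = build_universe(annotation, network)
    # only the core/peripheral partition is needed; the active list passed to
    # classify_genes does not influence it
    dummy = ActiveGeneList([universe.gene_ids[0]], universe)
    cls = classify_genes(set(target_terms), annotation, network, dummy, universe)
    probs = np.empty(len(universe))
    core = cls.core_genes
    peripheral = cls.peripheral_genes
    for i, g in enumerate(universe.gene_ids):
        if g in core:
            probs[i] = params.p1
        elif g in peripheral:
            probs[i] = params.p2
        else:
            probs[i] = params.q
    genes_arr = np.asarray(universe.gene_ids, dtype=object)
    for _ in range(max_redraws):
        draw = rng.random(len(universe)) < probs
        if draw.any():
            return ActiveGeneList(genes_arr[draw].tolist(), universe)
    raise RuntimeError(
        f"active gene list empty after {max_redraws} draws; "
        "check the generating probabilities"
    )


@dataclass(frozen=True)
class SimulationResult:
    """Pooled PR curves and the raw per-run scores of a study."""

    curves: dict[str, PRCurve]
    runs: dict[str, list[tuple[dict[str, float], set[str], list[str]]]]
    spec: SimulationSpec


Method = Literal["network", "network_free", "fisher_single_term"]


def _score_model_output(
    solution: EnrichmentSolution,
    annotation: AnnotationSet,
    active: ActiveGeneList,
    universe_size: int,
) -> dict[str, float]:
    """Bonferroni-corrected hypergeometric score for each output term."""
    m = annotation.n_terms
    scores = {}
    for t in solution.term_set:
        genes = annotation.genes_of(t)
        p = fisher_enrichment_p(
            ContingencyCounts(
                k=len(genes & active.gene_ids),
                K=len(genes),
                n=len(active),
                N=universe_size,
            )
        )
        scores[t] = bonferroni(p, m)
    return scores


def _score_all_terms(
    annotation: AnnotationSet, active: ActiveGeneList, universe_size: int
) -> dict[str, float]:
    m = annotation.n_terms
    out = {}
    for t in annotation.term_ids:
        genes = annotation.genes_of(t)
        p = fisher_enrichment_p(
            ContingencyCounts(
                k=len(genes & active.gene_ids),
                K=len(genes),
                n=len(active),
                N=universe_size,
            )
        )
        out[t] = bonferroni(p, m)
    return out


def run_simulation_study(
    world: SyntheticWorld,
    spec: SimulationSpec,
    methods: Sequence[Method] = ("network", "network_free", "fisher_single_term"),
    solving_params_mode: Literal["same_as_generating", "explicit"] = "same_as_generating",
    solving_params: Mapping[str, ModelParams] | None = None,
) -> SimulationResult:
    """Run the full benchmark and pool each method's outputs into a PR curve.

    For each of ``n_annotation_sets`` annotation subsamples and each of
    ``targets_per_set`` random target term sets, one active gene list is
    drawn and every method is run on it.  By default each model-based
    method solves with the generating parameters (the network-free variant
    uses only p1, q, alpha); ``solving_params_mode="explicit"`` overrides
    per method via ``solving_params``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    gen = spec.generating_params
    runs: dict[str, list] = {m: [] for m in methods}
    for _ in range(spec.n_annotation_sets):
        sub = subsample_annotation(
            world.annotation, spec.term_size_range, spec.terms_per_set, rng
        )
        universe = build_universe(sub, world.network)
        n_universe = len(universe)
        all_terms = sorted(sub.term_ids)
        for _ in range(spec.targets_per_set):
            target_idx = rng.choice(
                sub.n_terms, size=spec.active_terms_per_target, replace=False
            )
            targets = {sub.term_ids[i] for i in sorted(target_idx)}
            active = generate_active_genes(targets, sub, world.network, gen, rng)
            for method in methods:
                if method == "fisher_single_term":
                    scores = _score_all_terms(sub, active, n_universe)
                else:
                    if solving_params_mode == "explicit":
                        if solving_params is None or method not in solving_params:
                            raise ValueError(
                                f"explicit solving params missing for {method!r}"
                            )
                        sp = solving_params[method]
                    else:
                        sp = gen
                    variant = "network_free" if method == "network_free" else "network"
                    sol = greedy_search(sub, world.network, active, sp, variant=variant)
                    scores = _score_model_output(sol, sub, active, n_universe)
                runs[method].append((scores, set(targets), all_terms))
    curves = {m: pooled_pr_curve(runs[m]) for m in methods}
    return SimulationResult(curves=curves, runs=runs, spec=spec)
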