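"""Enrichment statistics: one-sided Fisher test, Bonferroni, pooled PR curves.

The one-sided Fisher exact test for over-representation equals the upper
tail of the hypergeometric distribution: with a universe of N genes, a gene
set of size K, and an active list of size n sharing k genes with the set,

    p = P(X >= k),   X ~ Hypergeometric(N, K, n).

The tail is summed in log space (log-binomials from a cached log-factorial
table) so that deep tails keep full relative precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import math

from scipy.special import gammaln

__all__ = [
    "ContingencyCounts",
    "PRCurve",
    "fisher_enrichment_p",
    "bonferroni",
    "pooled_pr_curve",
    "precision_envelope",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 overlap counts: k of the K set genes are among the n active of N."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need 0 <= K, n <= N, got K={self.K}, n={self.n}, N={self.N}")
        if not (max(0, self.K + self.n - self.N) <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"overlap k={self.k} impossible for K={self.K}, n={self.n}, N={self.N}"
            )


_lfact: list[float] = [0.0]  # log-factorial table, grown on demand


def _log_factorials(n: int) -> list[float]:
    global _lfact
    if len(_lfact) <= n:
        size = max(n + 1, 2 * len(_lfact))
        _lfact = gammaln(np.arange(size, dtype=float) + 1.0).tolist()
    return _lfact


def fisher_enrichment_p(counts: ContingencyCounts) -> float:
    """Upper-tail hypergeometric probability P(X >= k), exact in log space."""
    k, K, n, N = counts.k, counts.K, counts.n, counts.N
    if k <= max(0, K + n - N):
        return 1.0
    lf = _log_factorials(N)
    const = lf[N] - lf[n] - lf[N - n]
    # log C(K, x) + log C(N-K, n-x) - log C(N, n), summed by log-sum-exp
    logpmf = [
        lf[K] - lf[x] - lf[K - x]
        + lf[N - K] - lf[n - x] - lf[N - K - n + x]
        - const
        for x in range(k, min(K, n) + 1)
    ]
    top = max(logpmf)
    p = math.exp(top) * math.fsum(math.exp(v - top) for v in logpmf)
    return min(1.0, p)


def fisher_from_sets(
    gene_set: Iterable[str], active: Iterable[str], universe_size: int
) -> float:
    """Convenience: Fisher enrichment p of a gene set against an active list."""
    gs = set(gene_set)
    act = set(active)
    counts = ContingencyCounts(
        k=len(gs & act), K=len(gs), n=len(act), N=universe_size
    )
    return fisher_enrichment_p(counts)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return min(1.0, m * p)


@dataclass(frozen=True)
class PRCurve:
    """A pooled precision-recall curve over a grid of score cutoffs.

    At each cutoff c, counts are pooled across all runs: TP = true terms with
    score <= c, FP = non-true terms with score <= c, FN = true terms with
    score > c.  Precision at TP + FP = 0 is defined as 1 (no false calls).
    """

    cutoffs: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def to_rows(self) -> list[tuple[float, int, int, int, float, float]]:
        return [
            (float(c), int(tp), int(fp), int(fn), float(pr), float(rc))
            for c, tp, fp, fn, pr, rc in zip(
                self.cutoffs, self.tp, self.fp, self.fn, self.precision, self.recall
            )
        ]


def pooled_pr_curve(
    runs: Sequence[tuple[Mapping[str, float], Iterable[str]] | tuple],
    cutoffs: Sequence[float] | None = None,
) -> PRCurve:
    """Pool per-run term scores into one precision-recall curve.

    Parameters
    ----------
    runs
        Sequence of ``(scores, true_terms)`` or ``(scores, true_terms,
        all_terms)`` tuples.  ``scores`` maps term id to a significance score
        (smaller = more significant); terms in ``all_terms`` missing from
        ``scores`` are imputed a score of 1 so recall stays well defined.
    cutoffs
        Score cutoffs defining the curve points.  Defaults to the sorted
        distinct pooled scores (the exact curve).
    """
    if not runs:
        raise ValueError("need at least one run to pool")
    score_list: list[float] = []
    truth_list: list[bool] = []
    for run in runs:
        scores, true_terms = run[0], set(run[1])
        all_terms = list(run[2]) if len(run) > 2 and run[2] is not None else list(scores)
        for t in all_terms:
            score_list.append(float(scores.get(t, 1.0)))
            truth_list.append(t in true_terms)
    scores_arr = np.asarray(score_list)
    truth_arr = np.asarray(truth_list)
    if cutoffs is None:
        grid = np.unique(scores_arr)
    else:
        grid = np.sort(np.asarray(cutoffs, dtype=float))
    n_true = int(truth_arr.sum())

    order = np.argsort(scores_arr, kind="stable")
    sorted_scores = scores_arr[order]
    cum_true = np.cumsum(truth_arr[order])
    idx = np.searchsorted(sorted_scores, grid, side="right")
    tp = np.where(idx > 0, cum_true[np.maximum(idx - 1, 0)], 0)
    called = idx
    fp = called - tp
    fn = n_true - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(called > 0, tp / np.maximum(called, 1), 1.0)
        recall = tp / n_true if n_true > 0 else np.ones_like(tp, dtype=float)
    return PRCurve(
        cutoffs=grid,
        tp=tp.astype(int),
        fp=fp.astype(int),
        fn=fn.astype(int),
        precision=precision.astype(float),
        recall=np.asarray(recall, dtype=float),
    )


def precision_envelope(curve: PRCurve, recall_grid: Sequence[float]) -> np.ndarray:
    """Best precision attainable at recall >= r, for each r in the grid.

    This is the standard attainable-operating-point comparison for PR
    curves: a curve (weakly) dominates another if its envelope is pointwise
    >= the other's over a shared recall grid.  Grid values above the curve's
    maximum recall yield NaN.
    """
    order = np.argsort(curve.recall, kind="stable")
    rec = curve.recall[order]
    prec = curve.precision[order]
    # suffix maximum of precision over points with recall >= r
    suffix_max = np.maximum.accumulate(prec[::-1])[::-1]
    out = np.full(len(recall_grid), np.nan)
    for i, r in enumerate(recall_grid):
        j = np.searchsorted(rec, r, side="left")
        if j < len(rec):
            out[i] = suffix_max[j]
    return out
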