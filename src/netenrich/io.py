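"""Readers and writers for the file formats the tool touches.

GMT (one gene set per line: name, description, member genes) is the
annotation interchange format; networks are two-column edge lists (or
three-column SIF, interaction type ignored); gene lists are plain text,
one id per line.  Gene identifiers are opaque case-sensitive strings — no
symbol/accession mapping is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .core import AnnotationSet, GeneNetwork
from .search import EnrichmentSolution

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_gene_list",
    "write_results",
]


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file into an AnnotationSet.

    Each line must have at least three tab-separated fields (term id,
    description, one or more genes).  Duplicate genes within a line are
    de-duplicated with a warning; duplicate term ids are an error.
    """
    path = Path(path)
    gene_sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} lists no genes")
            if term in gene_sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate genes in term %s de-duplicated",
                    path,
                    lineno,
                    len(genes) - len(unique),
                    term,
                )
            gene_sets[term] = unique
            descriptions[term] = desc
    if not gene_sets:
        raise ValueError(f"{path}: no gene sets found")
    return AnnotationSet(gene_sets, descriptions)


def write_gmt(annotation: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as GMT (genes in lexicographic order)."""
    path = Path(path)
    with path.open("w") as fh:
        for term in annotation.term_ids:
            desc = annotation.descriptions.get(term, "")
            genes = sorted(annotation.genes_of(term))
            fh.write("\t".join([term, desc, *genes]) + "\n")


def _split_edge_line(line: str) -> list[str]:
    fields = line.split("\t")
    if len(fields) < 2:
        fields = line.split()
    return fields


def read_network(path: str | Path) -> GeneNetwork:
    """Read a two-column edge list (or three-column SIF) into a GeneNetwork.

    Self-loops and duplicate edges (including reversed duplicates) are
    removed, with counts logged.  An empty file yields an empty network.
    """
    path = Path(path)
    seen: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    n_self, n_dup = 0, 0
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_edge_line(line)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            if len(fields) >= 3:
                u, v = fields[0], fields[2]  # SIF: source, type, target
            else:
                u, v = fields[0], fields[1]
            if u == v:
                n_self += 1
                continue
            key = frozenset((u, v))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append((u, v))
    if n_self or n_dup:
        logger.info(
            "%s: removed %d self-loops and %d duplicate edges", path, n_self, n_dup
        )
    return GeneNetwork(edges)


def write_network(network: GeneNetwork, path: str | Path) -> None:
    """Write a GeneNetwork as a sorted two-column TSV edge list."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in network.edges():
            fh.write(f"{u}\t{v}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line file; blanks and '#' comments are ignored."""
    path = Path(path)
    genes: set[str] = set()
    with path.open(newline="") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line)
    if not genes:
        raise ValueError(f"{path}: no gene identifiers found")
    return genes


def write_results(
    solutions: Sequence[EnrichmentSolution],
    path: str | Path,
    annotation: AnnotationSet | None = None,
    header_lines: Iterable[str] = (),
) -> None:
    """Write solutions as a TSV, one block per parameter combination.

    Blocks are ordered by ascending super-pseudo-term p-value (ties keep
    the grid enumeration order: p1, p2, q each descending); within a block,
    terms are ranked by ascending single-term Fisher p-value with ties
    broken lexicographically by term id.
    """
    if not solutions:
        raise ValueError("no solutions to write")
    path = Path(path)
    ordered = sorted(
        enumerate(solutions),
        key=lambda pair: (
            pair[1].fisher_p,
            pair[1].grid_index if pair[1].grid_index is not None else pair[0],
        ),
    )
    with path.open("w") as fh:
        fh.write(f"# netenrich v{__version__}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "# block tie-break: grid enumeration order "
            "(p1 descending, p2 descending, q descending)\n"
        )
        for _, sol in ordered:
            p = sol.params
            fh.write(
                f"# combination\tp1={p.p1:g}\tp2={p.p2:g}\tq={p.q:g}\t"
                f"alpha={p.alpha:g}\tvariant={sol.variant}\t"
                f"combination_p={sol.fisher_p:.6g}\tn_terms={len(sol.term_set)}\n"
            )
            fh.write("rank\tterm_id\tdescription\tfisher_p\n")
            rows = sorted(
                sol.term_set, key=lambda t: (sol.term_pvalues.get(t, 1.0), t)
            )
            for rank, term in enumerate(rows, start=1):
                desc = (
                    annotation.descriptions.get(term, "")
                    if annotation is not None
                    else ""
                )
                fh.write(
                    f"{rank}\t{term}\t{desc}\t{sol.term_pvalues.get(term, 1.0):.6g}\n"
                )
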