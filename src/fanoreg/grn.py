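"""Directed gene regulatory network and the topological predicates used by
the inference step (ancestors, feedback-loop membership, per-gene status)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "GRN",
    "GRNStatus",
    "GRNParseError",
    "read_grn_edgelist",
    "ancestors",
    "in_feedback_loop",
    "has_self_loop",
    "grn_status",
]

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"regulator", "target", "source", "from", "to", "tf", "gene", "parent", "child"}


class GRNParseError(ValueError):
    """Malformed edge-list input."""


class GRNStatus(str, Enum):
    """Topological status of a gene relative to a known GRN."""

    ABSENT = "absent"
    IN_CYCLE = "in_cycle"
    NO_ANCESTORS = "no_ancestors"
    HAS_ANCESTORS_ACYCLIC = "has_ancestors_acyclic"
    SELF_LOOP_DECLARED = "self_loop_declared"


@dataclass
class GRN:
    """A directed graph of regulator -> target edges.

    Gene identifiers are case-sensitive strings.  Self-loops are permitted
    in the input but represent *declared* autoregulation: such genes are
    excluded from VMR-based inference downstream.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], genes: Iterable[str] = ()) -> "GRN":
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        g.add_edges_from(edges)
        return cls(graph=g)

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def read_grn_edgelist(
    path: str | Path,
    header: str | bool = "auto",
    extra_genes: Iterable[str] = (),
    case_insensitive: bool = False,
) -> GRN:
    """Read a two-column TSV edge list (regulator, target) into a :class:`GRN`.

    ``header='auto'`` skips a first line whose tokens look like column names.
    Duplicate edges are deduplicated.  ``extra_genes`` adds edge-less
    vertices (e.g. from a companion vertex-list file).  With
    ``case_insensitive=True`` all identifiers are upper-cased on input; the
    default matches identifiers exactly, since silent case-folding can cause
    false joins.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    n_parsed = n_skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                n_skipped += 1
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise GRNParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            a, b = parts[0], parts[1]
            if lineno == 1 and header in ("auto", True):
                # auto mode: skip only if *both* tokens look like column names
                if header is True or (
                    a.lower() in _HEADER_TOKENS and b.lower() in _HEADER_TOKENS
                ):
                    n_skipped += 1
                    continue
            if case_insensitive:
                a, b = a.upper(), b.upper()
            edges.append((a, b))
            n_parsed += 1
    if not edges and not extra_genes:
        logger.warning("%s: empty edge list, resulting GRN has no genes", path)
    genes = [g.upper() for g in extra_genes] if case_insensitive else list(extra_genes)
    grn = GRN.from_edges(edges, genes)
    logger.info(
        "%s: parsed %d edge rows (%d skipped), %d unique edges, %d genes",
        path, n_parsed, n_skipped, len(grn.edges), len(grn.genes),
    )
    return grn


def _check_member(grn: GRN, gene: str) -> None:
    if gene not in grn:
        raise KeyError(f"gene {gene!r} not in GRN")


def ancestors(grn: GRN, gene: str) -> set[str]:
    """All genes with a directed path (length >= 1) to ``gene``.

    ``gene`` itself is included exactly when it lies on a cycle through
    itself (including a self-loop).
    """
    _check_member(grn, gene)
    anc = set(nx.ancestors(grn.graph, gene))
    if grn.graph.has_edge(gene, gene) or in_feedback_loop(grn, gene):
        anc.add(gene)
    return anc


def has_self_loop(grn: GRN, gene: str) -> bool:
    _check_member(grn, gene)
    return grn.graph.has_edge(gene, gene)


def in_feedback_loop(grn: GRN, gene: str) -> bool:
    """True iff ``gene`` lies on a directed cycle of length >= 2.

    Equivalent to its strongly connected component having more than one
    vertex; self-loops are deliberately not counted (they are declared
    autoregulation, handled separately).
    """
    _check_member(grn, gene)
    scc = next(c for c in nx.strongly_connected_components(grn.graph) if gene in c)
    return len(scc) > 1


def grn_status(grn: GRN, gene: str) -> GRNStatus:
    """Classify a gene's position in the GRN for the decision procedure."""
    if gene not in grn:
        return GRNStatus.ABSENT
    if has_self_loop(grn, gene):
        return GRNStatus.SELF_LOOP_DECLARED
    if in_feedback_loop(grn, gene):
        return GRNStatus.IN_CYCLE
    if not ancestors(grn, gene):
        return GRNStatus.NO_ANCESTORS
    return GRNStatus.HAS_ANCESTORS_ACYCLIC
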