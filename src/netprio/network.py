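"""Undirected protein–protein interaction (PPI) networks and seed-gene lists.

The whole prioritization pipeline operates on a simple undirected graph
whose nodes are gene symbols.  Every similarity index only needs two
queries against that graph: the neighbor set ``Γ(x)`` and the degree
``k_x = |Γ(x)|``.  :class:`PPINetwork` wraps a :class:`networkx.Graph`
and exposes exactly those queries, guaranteeing the invariants the
indices rely on (symmetry, no self-loops, no parallel edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "SeedSet",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
]

# Tokens commonly found in the header row of public interaction exports.
_HEADER_TOKENS = {
    "gene", "gene1", "gene2", "genea", "geneb", "protein", "protein1",
    "protein2", "interactor", "interactor_a", "interactor_b", "node",
    "node1", "node2", "source", "target", "symbol", "symbol_a", "symbol_b",
}


class PPINetwork:
    """Undirected simple graph over gene symbols.

    Invariants (enforced at construction):

    * symmetry: ``y in neighbors(x)`` iff ``x in neighbors(y)``
    * no self-loops, no parallel edges
    * ``sum(degree) == 2 * n_edges``
    """

    def __init__(self, graph: nx.Graph):
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("PPINetwork requires a simple undirected graph")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            graph = graph.copy()
            graph.remove_edges_from(loops)
        self._g = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        g.add_edges_from((x, y) for x, y in edges if x != y)
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def neighbors(self, gene: str) -> set[str]:
        """Γ(gene): the set of interaction partners. Never contains ``gene``."""
        self._check(gene)
        return set(self._g[gene])

    def degree(self, gene: str) -> int:
        """k_gene = |Γ(gene)|."""
        self._check(gene)
        return self._g.degree[gene]

    def edges(self) -> Iterable[tuple[str, str]]:
        return self._g.edges()

    def _check(self, gene: str) -> None:
        if gene not in self._g:
            raise KeyError(f"gene not in network: {gene!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class SeedSet:
    """Known disease-associated genes anchoring a prioritization run.

    ``genes`` preserves input order and contains no duplicates.
    """

    disease_name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"empty seed set for disease {self.disease_name!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate symbols in seed set")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower().replace(" ", "_") in _HEADER_TOKENS for f in fields[:2])


def read_edge_list(path: str | Path, dialect: str = "tsv") -> PPINetwork:
    """Load an undirected network from a tab-separated edge list.

    ``dialect="tsv"``: columns 1–2 are the interactors; an optional header
    row is auto-detected from common column names.  ``dialect="sif"``:
    column 1 interacts with each of columns 3..n, column 2 being the
    relation label.

    Duplicate rows (in either orientation) collapse to a single edge and
    self-interaction rows are dropped; both are counted and logged.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'sif'")
    path = Path(path)
    g = nx.Graph()
    n_self, n_dup = 0, 0

    def add(x: str, y: str) -> None:
        nonlocal n_self, n_dup
        x, y = x.strip(), y.strip()
        if not x or not y:
            return
        if x == y:
            n_self += 1
            return
        if g.has_edge(x, y):
            n_dup += 1
        else:
            g.add_edge(x, y)

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                # tolerate whitespace-separated exports
                fields = line.split()
            if lineno == 1 and dialect == "tsv" and _looks_like_header(fields):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            if dialect == "tsv":
                add(fields[0], fields[1])
            else:  # sif: node, relation, partners...
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: malformed SIF row at line {lineno}: {line!r}"
                    )
                for partner in fields[2:]:
                    add(fields[0], partner)

    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges")
    if n_self:
        logger.warning("%s: dropped %d self-interaction row(s)", path, n_self)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge row(s)", path, n_dup)
    return PPINetwork(g)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the network back out as a two-column TSV (sorted, canonical)."""
    path = Path(path)
    with path.open("w") as fh:
        for x, y in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{x}\t{y}\n")


def read_gene_list(path: str | Path, disease_name: str) -> SeedSet:
    """Read a plain-text gene list: one symbol per line, ``#`` comments.

    Order is preserved; duplicates keep the first occurrence (logged).
    """
    path = Path(path)
    seen: dict[str, None] = {}
    n_dup = 0
    with path.open() as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym in seen:
                n_dup += 1
            else:
                seen[sym] = None
    if not seen:
        raise ValueError(f"{path}: empty seed set")
    if n_dup:
        logger.warning("%s: removed %d duplicate symbol(s)", path, n_dup)
    return SeedSet(disease_name=disease_name, genes=tuple(seen))
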