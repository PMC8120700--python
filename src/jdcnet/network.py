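"""Protein–protein interaction (PPI) networks as undirected simple graphs.

The network defines the universe of scored proteins.  Node identifiers are
opaque, case-sensitive strings; self-interactions and repeated interactions
are dropped at parse time, so every :class:`PPINetwork` is a simple graph.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "read_ppi", "write_ppi"]


class PPINetwork:
    """Undirected simple graph over protein IDs.

    Thin wrapper around :class:`networkx.Graph` enforcing the invariants
    needed by edge-clustering scores: no self-loops, no parallel edges,
    string node IDs.  Isolated nodes are permitted.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                continue
            g.add_edge(a, b)
        self._g = g

    # -- container protocol -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (shared, not a copy)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._g.edges}

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, i: str, j: str) -> bool:
        return self._g.has_edge(i, j)

    # -- primitives consumed by scoring -------------------------------------

    def degree(self, i: str) -> int:
        """Number of distinct neighbours of ``i`` (k_i)."""
        if i not in self._g:
            raise KeyError(f"unknown node: {i!r}")
        return self._g.degree[i]

    def neighbors(self, i: str) -> set[str]:
        """The neighbourhood D_i of node ``i``."""
        if i not in self._g:
            raise KeyError(f"unknown node: {i!r}")
        return set(self._g.neighbors(i))

    def common_neighbor_count(self, i: str, j: str) -> int:
        """|D_i ∩ D_j| — for an edge {i,j}, the number of triangles through it."""
        if i == j:
            raise ValueError(f"common_neighbor_count requires distinct nodes, got {i!r} twice")
        if i not in self._g:
            raise KeyError(f"unknown node: {i!r}")
        if j not in self._g:
            raise KeyError(f"unknown node: {j!r}")
        return sum(1 for _ in nx.common_neighbors(self._g, i, j))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PPINetwork({len(self)} nodes, {self.number_of_edges()} edges)"


def read_ppi(path: str | Path) -> PPINetwork:
    """Parse a two-column edge list into a :class:`PPINetwork`.

    Lines starting with ``#`` are comments; columns beyond the first two are
    ignored (DIP/BioGRID exports carry extra columns).  Self-interactions and
    repeated interactions (either orientation) are silently dropped; the
    counts are logged.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If a non-comment line has fewer than two fields (names the line number).
    """
    path = Path(path)
    g = nx.Graph()
    n_self = n_dup = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                g.add_node(a)  # the protein itself stays in the universe
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_self or n_dup:
        logger.info(
            "read_ppi(%s): dropped %d self-interactions and %d repeated interactions",
            path, n_self, n_dup,
        )
    net = PPINetwork()
    net._g = g
    return net


def write_ppi(net: PPINetwork, path: str | Path) -> Path:
    """Serialise as two-column TSV: smaller ID first per edge, rows sorted.

    Isolated nodes cannot be represented in an edge list and are omitted;
    round-trips are exact for networks without them.
    """
    path = Path(path)
    rows = sorted(tuple(sorted(e)) for e in net.edges)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
    return path
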