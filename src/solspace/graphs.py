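"""Graph container, file I/O, information-preserving permutation and benchmark generators.

The central object is :class:`Graph`: an undirected, optionally edge-weighted
graph whose *storage order* (the order of the node list and of the edge list)
is an explicit, first-class property.  Storage order is what community
detection implementations actually consume, and order sensitivity is exactly
the bias this package measures, so two graphs that are equal as abstract
graphs but differently ordered are deliberately distinct objects here.

:func:`permute` produces an information-preserving permutation: same abstract
graph (identical node identifiers, adjacency and weights), new storage order.

Generators build the standard benchmarks used throughout: the ring of cliques
(``RC``), the ring of cliques with a central hub node (``RC+C``) whose
symmetric attachments make it a controlled outlier, and the Erdős–Rényi
G(n, p) null model.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GraphParseError",
    "GraphValidationError",
    "RingOfCliquesSpec",
    "ring_of_cliques",
    "erdos_renyi",
    "permute",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
]


class GraphValidationError(ValueError):
    """A graph, spec or edge violates a structural invariant."""


class GraphParseError(ValueError):
    """A graph file could not be parsed; the message names the offending line."""


def _ukey(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered key of an edge."""
    return (u, v) if u <= v else (v, u)


class Graph:
    """Undirected graph with ordered node and edge storage.

    Parameters
    ----------
    nodes:
        Node identifiers (strings) in storage order.  Must be unique.
    edges:
        ``(u, v)`` or ``(u, v, weight)`` tuples in storage order.  Self-loops
        and duplicate undirected edges are rejected; weights must be positive
        and default to 1.0.
    """

    __slots__ = ("nodes", "edges", "_index")

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple] = (),
    ) -> None:
        self.nodes: list[str] = [str(n) for n in nodes]
        if len(self.nodes) < 1:
            raise GraphValidationError("a graph must have at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphValidationError("node identifiers must be unique")
        self._index = {n: i for i, n in enumerate(self.nodes)}

        norm: list[tuple[str, str, float]] = []
        seen: set[tuple[str, str]] = set()
        for e in edges:
            if len(e) == 2:
                u, v, w = str(e[0]), str(e[1]), 1.0
            elif len(e) == 3:
                u, v, w = str(e[0]), str(e[1]), float(e[2])
            else:
                raise GraphValidationError(f"edge {e!r} is not a 2- or 3-tuple")
            if u == v:
                raise GraphValidationError(f"self-loop on node {u!r} is not allowed")
            if u not in self._index or v not in self._index:
                raise GraphValidationError(f"edge ({u!r}, {v!r}) has an endpoint not in the node list")
            if w <= 0 or not math.isfinite(w):
                raise GraphValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
            key = _ukey(u, v)
            if key in seen:
                raise GraphValidationError(f"duplicate undirected edge ({u!r}, {v!r})")
            seen.add(key)
            norm.append((u, v, w))
        self.edges: list[tuple[str, str, float]] = norm

    # -- basic accessors ---------------------------------------------------

    @property
    def n_v(self) -> int:
        return len(self.nodes)

    @property
    def n_e(self) -> int:
        return len(self.edges)

    @property
    def is_weighted(self) -> bool:
        return any(w != 1.0 for _, _, w in self.edges)

    def node_index(self, node: str) -> int:
        return self._index[node]

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v, _ in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def degree_sequence(self) -> tuple[int, ...]:
        """Node degrees in non-increasing order (storage-order insensitive)."""
        deg = Counter()
        for u, v, _ in self.edges:
            deg[u] += 1
            deg[v] += 1
        return tuple(sorted((deg[n] for n in self.nodes), reverse=True))

    def edge_multiset(self) -> Counter:
        """Multiset of undirected weighted edges, the order-free fingerprint."""
        return Counter((*_ukey(u, v), w) for u, v, w in self.edges)

    def same_abstract_graph(self, other: "Graph") -> bool:
        """True iff the two graphs are equal up to storage order."""
        return set(self.nodes) == set(other.nodes) and self.edge_multiset() == other.edge_multiset()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_v={self.n_v}, n_e={self.n_e}, weighted={self.is_weighted})"


# -- permutation -----------------------------------------------------------


def permute(g: Graph, seed: int) -> Graph:
    """Information-preserving permutation of ``g``.

    Draws a uniform random permutation of the node list, independently
    shuffles the edge list, and swaps each edge's endpoint order with
    probability one half.  Node identifiers, adjacency and weights are
    untouched: the result is the same abstract graph in a new storage order.
    """
    rng = np.random.default_rng(seed)
    nodes = [g.nodes[i] for i in rng.permutation(g.n_v)]
    edges = [g.edges[i] for i in rng.permutation(g.n_e)]
    flips = rng.random(len(edges)) < 0.5
    edges = [(v, u, w) if f else (u, v, w) for (u, v, w), f in zip(edges, flips)]
    return Graph(nodes, edges)


# -- generators ------------------------------------------------------------


@dataclass(frozen=True)
class RingOfCliquesSpec:
    """Specification of a ring-of-cliques benchmark.

    ``n_cliques`` complete subgraphs of ``clique_size`` nodes each, joined in
    a single cycle by one edge between consecutive cliques.  For
    ``n_cliques == 2`` the cycle degenerates: the two cliques are joined by
    exactly one edge (a cycle would duplicate it).  With ``central_node`` a
    hub node is added, connected once to each clique (to its lowest-index
    member), creating a symmetric outlier.
    """

    n_cliques: int
    clique_size: int
    central_node: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cliques < 2:
            raise GraphValidationError("n_cliques must be at least 2")
        if self.clique_size < 3:
            raise GraphValidationError("clique_size must be at least 3")

    @property
    def n_ring_edges(self) -> int:
        return 1 if self.n_cliques == 2 else self.n_cliques

    @property
    def n_nodes(self) -> int:
        return self.n_cliques * self.clique_size + (1 if self.central_node else 0)

    def clique_members(self, i: int) -> list[str]:
        return [f"c{i}_n{j}" for j in range(self.clique_size)]


CENTRE = "centre"


def ring_of_cliques(spec: RingOfCliquesSpec) -> Graph:
    """Build the RC / RC+C benchmark graph from ``spec`` (deterministic)."""
    nodes: list[str] = []
    edges: list[tuple[str, str, float]] = []
    for i in range(spec.n_cliques):
        members = spec.clique_members(i)
        nodes.extend(members)
        for a in range(spec.clique_size):
            for b in range(a + 1, spec.clique_size):
                edges.append((members[a], members[b], 1.0))
    # one cycle through the cliques; for two cliques a single bridging edge
    for i in range(spec.n_ring_edges):
        j = (i + 1) % spec.n_cliques
        edges.append((f"c{i}_n0", f"c{j}_n0", 1.0))
    if spec.central_node:
        nodes.append(CENTRE)
        for i in range(spec.n_cliques):
            edges.append((CENTRE, f"c{i}_n0", 1.0))
    return Graph(nodes, edges)


def erdos_renyi(n: int, p: float, seed: int) -> Graph:
    """Sample an Erdős–Rényi G(n, p) graph with nodes ``v0..v{n-1}``."""
    if not 0.0 <= p <= 1.0:
        raise GraphValidationError("p must be in [0, 1]")
    if n < 1:
        raise GraphValidationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < p
    edges = [(nodes[i], nodes[j], 1.0) for i, j in zip(iu[mask], ju[mask])]
    return Graph(nodes, edges)


# -- edge-list I/O ---------------------------------------------------------

_HEADER_NAMES = {"source", "target", "from", "to", "u", "v", "node1", "node2", "weight", "w"}


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_edgelist(path, delimiter: str = ",", weighted: bool | None = None) -> Graph:
    """Read an undirected graph from a delimited edge-list file.

    Columns are ``source, target[, weight]``.  A header row is auto-detected:
    either its names match common header vocabulary, or a third column that
    is non-numeric marks it as a header.  ``weighted=None`` infers weighting
    from the column count of the first data row.  Node order is
    first-appearance order.  Duplicate undirected edges are collapsed with
    their weights summed, with a warning.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            fields = [f.strip() for f in raw]
            if not fields or all(f == "" for f in fields):
                continue
            rows.append((lineno, fields))
    if not rows:
        raise GraphParseError(f"{path}: file contains no rows")

    first = rows[0][1]
    is_header = all(f.lower() in _HEADER_NAMES for f in first[: len(first)]) or (
        len(first) >= 3 and not _is_number(first[2])
    )
    if is_header:
        rows = rows[1:]
        if not rows:
            raise GraphParseError(f"{path}: header only, no data rows")
    if weighted is None:
        weighted = len(rows[0][1]) >= 3

    expected = 3 if weighted else 2
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    weights: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for lineno, fields in rows:
        if len(fields) < expected:
            raise GraphParseError(
                f"{path}: line {lineno}: expected {expected} fields, found {len(fields)}"
            )
        u, v = fields[0], fields[1]
        if weighted:
            if not _is_number(fields[2]):
                raise GraphParseError(f"{path}: line {lineno}: weight {fields[2]!r} is not a number")
            w = float(fields[2])
            if w <= 0:
                raise GraphValidationError(f"{path}: line {lineno}: non-positive weight {w}")
        else:
            w = 1.0
        if u == v:
            raise GraphValidationError(f"{path}: line {lineno}: self-loop on {u!r}")
        for x in (u, v):
            if x not in seen_nodes:
                seen_nodes.add(x)
                nodes.append(x)
        key = _ukey(u, v)
        if key in weights:
            logger.warning("%s: line %d: duplicate edge (%s, %s) collapsed, weights summed", path, lineno, u, v)
            weights[key] += w
        else:
            weights[key] = w
            order.append(key)
    return Graph(nodes, [(u, v, weights[(u, v)]) for u, v in order])


def write_edgelist(g: Graph, path, delimiter: str = ",", header: bool = True) -> None:
    """Write ``g`` as a three-column ``source, target, weight`` file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if header:
            writer.writerow(["source", "target", "weight"])
        for u, v, w in g.edges:
            writer.writerow([u, v, repr(w) if w != int(w) else int(w)])


# -- GraphML I/O -----------------------------------------------------------


def read_graphml(path) -> Graph:
    """Read an undirected graph from GraphML; directed graphs are rejected."""
    nxg = nx.read_graphml(path)
    if nxg.is_directed():
        raise GraphValidationError(f"{path}: directed graphs are not supported")
    if nxg.number_of_nodes() == 0:
        raise GraphParseError(f"{path}: GraphML file defines no nodes")
    edges = [(u, v, float(d.get("weight", 1.0))) for u, v, d in nxg.edges(data=True)]
    return Graph(list(nxg.nodes()), edges)


def write_graphml(g: Graph, path) -> None:
    """Write ``g`` to GraphML, preserving node order and weights."""
    nxg = nx.Graph()
    nxg.add_nodes_from(g.nodes)
    for u, v, w in g.edges:
        nxg.add_edge(u, v, weight=w)
    nx.write_graphml(nxg, path)
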