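"""Partitions of a node set: similarity, exact uniqueness matching and validity.

A :class:`Partition` assigns every node exactly one community label.  Labels
are opaque: two partitions are the *same solution* iff they induce the same
set partition of the nodes, regardless of label names.  Matching therefore
uses an exact canonical form rather than a floating-point NMI comparison
(the two are equivalent where it matters: NMI equals 1 exactly on identical
set partitions).

Validity checks encode the minimal requirements a community structure must
meet: not everything in one community, not every node a singleton, every
community internally connected.  A partition with more inter-community than
intra-community edges is structurally *degenerate* — it contradicts the very
definition of a community — and is flagged independently of validity so that
downstream policy can decide whether degeneracy disqualifies a solution.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Hashable, Mapping

from sklearn.metrics import normalized_mutual_info_score

from .graphs import Graph

__all__ = [
    "Partition",
    "ValidityReport",
    "nmi",
    "same_partition",
    "validate",
    "ALL_ONE_COMMUNITY",
    "ALL_SINGLETONS",
    "DISCONNECTED_COMMUNITY",
    "INTER_GT_INTRA",
    "read_partition_csv",
    "write_partition_csv",
    "read_partition_json",
    "write_partition_json",
]

ALL_ONE_COMMUNITY = "ALL_ONE_COMMUNITY"
ALL_SINGLETONS = "ALL_SINGLETONS"
DISCONNECTED_COMMUNITY = "DISCONNECTED_COMMUNITY"
INTER_GT_INTRA = "INTER_GT_INTRA"

#: Reason codes that make a partition invalid (degeneracy is tracked apart).
INVALIDITY_CODES = (ALL_ONE_COMMUNITY, ALL_SINGLETONS, DISCONNECTED_COMMUNITY)


class Partition:
    """Disjoint, exhaustive assignment of nodes to community labels."""

    __slots__ = ("assignment", "_canonical")

    def __init__(self, assignment: Mapping[str, Hashable]) -> None:
        if not assignment:
            raise ValueError("a partition must cover at least one node")
        self.assignment: dict[str, Hashable] = dict(assignment)
        self._canonical: tuple[tuple[str, ...], ...] | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.assignment)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.assignment)

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[frozenset[str]]:
        """Communities as node sets, ordered by first node appearance."""
        by_label: dict[Hashable, list[str]] = {}
        for node, label in self.assignment.items():
            by_label.setdefault(label, []).append(node)
        return [frozenset(members) for members in by_label.values()]

    def canonical_labels(self) -> dict[str, int]:
        """Relabel communities 0..k-1 in order of first node appearance."""
        mapping: dict[Hashable, int] = {}
        out: dict[str, int] = {}
        for node, label in self.assignment.items():
            if label not in mapping:
                mapping[label] = len(mapping)
            out[node] = mapping[label]
        return out

    def canonical_form(self) -> tuple[tuple[str, ...], ...]:
        """Label-free canonical representation: sorted tuple of sorted blocks.

        Identical tokens iff identical set partitions; the full block
        representation is kept (no hashing) so equality is exact.
        """
        if self._canonical is None:
            blocks = sorted(tuple(sorted(c)) for c in self.communities())
            self._canonical = tuple(blocks)
        return self._canonical

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.canonical_form() == other.canonical_form()

    def __hash__(self) -> int:
        return hash(self.canonical_form())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Partition(n={len(self.assignment)}, k={self.k})"


def _check_same_nodes(p1: Partition, p2: Partition) -> list[str]:
    if p1.node_set != p2.node_set:
        raise ValueError("partitions are defined on different node sets")
    return sorted(p1.node_set)


_NMI_AVERAGE = {"arithmetic": "arithmetic", "min": "min", "max": "max", "sqrt": "geometric"}


def nmi(p1: Partition, p2: Partition, normalization: str = "arithmetic") -> float:
    """Normalised mutual information between two partitions, in [0, 1].

    Label-permutation invariant; equals 1 iff the partitions are identical
    as set partitions.  ``normalization`` picks the entropy normaliser
    (``arithmetic`` mean by default; ``min``, ``max`` and ``sqrt`` i.e.
    geometric are accepted) — all variants agree on the NMI = 1 predicate.
    """
    if normalization not in _NMI_AVERAGE:
        raise ValueError(f"unknown normalization {normalization!r}")
    order = _check_same_nodes(p1, p2)
    a1 = p1.canonical_labels()
    a2 = p2.canonical_labels()
    x = [a1[n] for n in order]
    y = [a2[n] for n in order]
    return float(normalized_mutual_info_score(x, y, average_method=_NMI_AVERAGE[normalization]))


def same_partition(p1: Partition, p2: Partition) -> bool:
    """Exact identity of the induced set partitions (the NMI = 1 predicate)."""
    _check_same_nodes(p1, p2)
    return p1.canonical_form() == p2.canonical_form()


@dataclass
class ValidityReport:
    """Outcome of the structural checks on one partition of one graph."""

    is_valid: bool
    is_degenerate: bool
    reasons: list[str] = field(default_factory=list)
    community_connected: list[bool] = field(default_factory=list)
    intra_edges: float = 0.0
    inter_edges: float = 0.0

    def to_dict(self) -> dict:
        return {
            "is_valid": self.is_valid,
            "is_degenerate": self.is_degenerate,
            "reasons": list(self.reasons),
            "community_connected": list(self.community_connected),
            "intra_edges": self.intra_edges,
            "inter_edges": self.inter_edges,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidityReport":
        return cls(
            is_valid=d["is_valid"],
            is_degenerate=d["is_degenerate"],
            reasons=list(d["reasons"]),
            community_connected=list(d["community_connected"]),
            intra_edges=d["intra_edges"],
            inter_edges=d["inter_edges"],
        )


def _connected(members: frozenset[str], adj: dict[str, set[str]]) -> bool:
    """Undirected connectivity of the induced subgraph; singletons connected."""
    if len(members) <= 1:
        return True
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in members and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(members)


def validate(g: Graph, p: Partition, weighted: bool = False) -> ValidityReport:
    """Check ``p`` against the minimal community requirements on ``g``.

    Invalidity reasons: a single all-encompassing community (k = 1), all
    nodes singletons (k = n_v), or any community of two or more nodes whose
    induced subgraph is disconnected.  Degeneracy (tracked separately): the
    inter-community edge count exceeds the intra-community edge count,
    globally; ``weighted=True`` switches the comparison to edge weights.
    """
    if p.node_set != frozenset(g.nodes):
        raise ValueError("partition does not cover exactly the graph's node set")
    reasons: list[str] = []
    k = p.k
    if k == 1:
        reasons.append(ALL_ONE_COMMUNITY)
    if k == g.n_v and g.n_v > 1:
        reasons.append(ALL_SINGLETONS)

    adj = g.adjacency()
    connected_flags = [_connected(c, adj) for c in p.communities()]
    if not all(connected_flags):
        reasons.append(DISCONNECTED_COMMUNITY)

    intra = inter = 0.0
    for u, v, w in g.edges:
        x = w if weighted else 1.0
        if p.assignment[u] == p.assignment[v]:
            intra += x
        else:
            inter += x
    degenerate = inter > intra
    if degenerate:
        reasons.append(INTER_GT_INTRA)

    return ValidityReport(
        is_valid=not any(r in INVALIDITY_CODES for r in reasons),
        is_degenerate=degenerate,
        reasons=reasons,
        community_connected=connected_flags,
        intra_edges=intra,
        inter_edges=inter,
    )


# -- I/O -------------------------------------------------------------------


def write_partition_csv(p: Partition, path) -> None:
    """Two-column ``node,community`` CSV with canonical integer labels."""
    labels = p.canonical_labels()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "community"])
        for node in p.assignment:
            writer.writerow([node, labels[node]])


def read_partition_csv(path) -> Partition:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0][:2] == ["node", "community"]:
        rows = rows[1:]
    return Partition({node: label for node, label, *_ in rows if node})


def write_partition_json(p: Partition, path) -> None:
    with open(path, "w") as fh:
        json.dump(p.canonical_labels(), fh, indent=1)


def read_partition_json(path) -> Partition:
    with open(path) as fh:
        return Partition(json.load(fh))
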