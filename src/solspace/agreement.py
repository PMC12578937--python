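"""Pairwise agreement matrix and per-node outlier profiles.

The agreement matrix weighs co-classification by solution probability:

    gamma_uv = sum_i p_i * chi_i(u, v)

where ``chi_i(u, v)`` is 1 when nodes u and v share a community in solution
``P_i``.  Node pairs that always travel together have gamma 1; pairs that
never co-occur have gamma exactly 0 (probabilities are finite sums, so zero
entries are exact) and are excluded from profile means.

A node's profile summarises its row: ``gamma_bar_plus`` is the mean of the
non-zero off-diagonal entries.  Stable nodes sit near 1.0; nodes whose
membership flips between solutions — outliers — sit low.  Because the mean
over *all* non-zero partners dilutes a stable clique node's 1.0 entries with
its weaker cross-links, the profile also reports ``mean_top_agreement``, the
mean over the partners attaining the node's maximum agreement (the
"relative to each other" reading of within-community stability); both views
are emitted, never silently merged.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .explorer import ExplorationResult
from .partitions import Partition

__all__ = [
    "AgreementMatrix",
    "OutlierProfile",
    "agreement_matrix",
    "agreement_from_result",
    "outlier_profiles",
    "write_agreement_csv",
    "write_profiles_csv",
]


@dataclass
class AgreementMatrix:
    """Symmetric ``n_v x n_v`` matrix of probability-weighted co-classification."""

    nodes: list[str]
    gamma: np.ndarray
    n_solutions: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        n = len(self.nodes)
        if self.gamma.shape != (n, n):
            raise ValueError("gamma must be square over the node list")

    def value(self, u: str, v: str) -> float:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return float(self.gamma[i, j])


def agreement_matrix(
    solutions: Sequence[Partition],
    probs: Sequence[float],
    nodes: Optional[Sequence[str]] = None,
) -> AgreementMatrix:
    """Build the agreement matrix from solutions and their probabilities.

    ``probs`` must be nonnegative and sum to one (within 1e-9).  All
    partitions must cover the same node set; ``nodes`` fixes the row order
    (default: first partition's node order).
    """
    if len(solutions) == 0:
        raise ValueError("at least one solution is required")
    if len(probs) != len(solutions):
        raise ValueError("probs must match solutions in length")
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(float(p.sum()) - 1.0) > 1e-9:
        raise ValueError("probs must be nonnegative and sum to 1")

    node_set = solutions[0].node_set
    for s in solutions[1:]:
        if s.node_set != node_set:
            raise ValueError("all solutions must cover the same node set")
    node_order = list(nodes) if nodes is not None else solutions[0].nodes
    if frozenset(node_order) != node_set:
        raise ValueError("node order must cover exactly the solutions' node set")

    n = len(node_order)
    gamma = np.zeros((n, n))
    for prob, part in zip(p, solutions):
        labels = part.canonical_labels()
        vec = np.array([labels[u] for u in node_order])
        gamma += prob * (vec[:, None] == vec[None, :])
    return AgreementMatrix(nodes=node_order, gamma=gamma, n_solutions=len(solutions), probabilities=p)


def agreement_from_result(result: ExplorationResult) -> AgreementMatrix:
    """Agreement matrix of an exploration, weighted by the posterior means."""
    p_hat, _ = result.model.posterior()
    return agreement_matrix(result.solutions, p_hat)


@dataclass
class OutlierProfile:
    """Scalar summary of one node's agreement row."""

    node: str
    gamma_bar_plus: float  # mean of non-zero off-diagonal entries; NaN if none
    mean_top_agreement: float  # mean over partners at the node's maximum agreement
    n_nonzero_partners: int
    is_outlier: bool

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "gamma_bar_plus": self.gamma_bar_plus,
            "mean_top_agreement": self.mean_top_agreement,
            "n_nonzero_partners": self.n_nonzero_partners,
            "is_outlier": self.is_outlier,
        }


def outlier_profiles(m: AgreementMatrix, threshold: float = 0.5) -> list[OutlierProfile]:
    """Per-node profiles; a node is flagged when ``gamma_bar_plus < threshold``.

    A node with no non-zero off-diagonal entry (it never co-occurred with
    anyone) gets NaN means, zero partners, and is flagged as an outlier.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    profiles = []
    n = len(m.nodes)
    for i, node in enumerate(m.nodes):
        row = np.delete(m.gamma[i], i)
        nz = row[row > 0]
        if nz.size == 0:
            profiles.append(OutlierProfile(node, math.nan, math.nan, 0, True))
            continue
        gbp = float(nz.mean())
        top = float(nz[np.isclose(nz, nz.max())].mean())
        profiles.append(OutlierProfile(node, gbp, top, int(nz.size), gbp < threshold))
    return profiles


# -- output ----------------------------------------------------------------

#: Above this node count the dense CSV becomes unwieldy; triplets are used.
DENSE_LIMIT = 200


def write_agreement_csv(m: AgreementMatrix, path, dense_limit: int = DENSE_LIMIT) -> None:
    """Write gamma as dense CSV (header = node ids) or, above ``dense_limit``
    nodes, as a sparse ``u,v,gamma`` triplet CSV of the non-zero upper triangle."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if len(m.nodes) <= dense_limit:
            writer.writerow(["node"] + m.nodes)
            for node, row in zip(m.nodes, m.gamma):
                writer.writerow([node] + [f"{x:.10g}" for x in row])
        else:
            writer.writerow(["u", "v", "gamma"])
            for i, u in enumerate(m.nodes):
                for j in range(i + 1, len(m.nodes)):
                    if m.gamma[i, j] > 0:
                        writer.writerow([u, m.nodes[j], f"{m.gamma[i, j]:.10g}"])


def write_profiles_csv(profiles: Sequence[OutlierProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "gamma_bar_plus", "mean_top_agreement", "n_nonzero_partners", "is_outlier"])
        for p in profiles:
            writer.writerow(
                [p.node, f"{p.gamma_bar_plus:.10g}", f"{p.mean_top_agreement:.10g}", p.n_nonzero_partners, p.is_outlier]
            )
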