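"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Beta quantile oracle
inverts a numerically integrated density instead of calling a distribution's
ppf, and the agreement oracle is a literal double loop over node pairs and
partitions.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


def beta_quantile(q: float, a: float, b: float) -> float:
    """Quantile of Beta(a, b) by root-finding on the integrated density."""
    log_beta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)

    def pdf(x: float) -> float:
        if x <= 0.0 or x >= 1.0:
            return 0.0
        return math.exp((a - 1) * math.log(x) + (b - 1) * math.log1p(-x) - log_beta)

    def cdf(x: float) -> float:
        val, _ = quad(pdf, 0.0, x, limit=300)
        return val

    return brentq(lambda x: cdf(x) - q, 1e-14, 1 - 1e-14, xtol=1e-13)


def credible_intervals(counts, gamma0: float, level: float) -> np.ndarray:
    """Equal-tailed marginal intervals of Dirichlet(gamma0 + c), by the quad oracle."""
    c = np.asarray(counts, dtype=float)
    k = len(c)
    t = c.sum()
    alpha = 1.0 - level
    out = np.empty((k, 2))
    for i in range(k):
        a = gamma0 + c[i]
        b = (k - 1) * gamma0 + t - c[i]
        out[i, 0] = beta_quantile(alpha / 2.0, a, b)
        out[i, 1] = beta_quantile(1.0 - alpha / 2.0, a, b)
    return out


def stabilisation_predicate(intervals: np.ndarray, delta: float) -> bool:
    return bool(np.max(intervals[:, 1] - intervals[:, 0]) <= delta)


def separation_predicate(intervals: np.ndarray):
    """Return the dominant index if one lower bound beats all other uppers, else None."""
    k = intervals.shape[0]
    for i in range(k):
        others = [intervals[j, 1] for j in range(k) if j != i]
        if others and intervals[i, 0] > max(others):
            return i
    return None


def brute_force_agreement(partitions, probs, node_order) -> np.ndarray:
    """Direct double-sum definition of the agreement matrix."""
    n = len(node_order)
    gamma = np.zeros((n, n))
    for p, part in zip(probs, partitions):
        for i, u in enumerate(node_order):
            for j, v in enumerate(node_order):
                if part.assignment[u] == part.assignment[v]:
                    gamma[i, j] += p
    return gamma


def all_set_partitions(items):
    """Enumerate every set partition of ``items`` (small inputs only)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def random_partition(nodes, rng) -> dict:
    """Uniformly random assignment of nodes to at most len(nodes) labels."""
    labels = rng.integers(0, len(nodes), size=len(nodes))
    return {n: int(l) for n, l in zip(nodes, labels)}


def random_small_graph(rng, n_max: int = 6):
    """Random connected-ish simple graph on at most ``n_max`` nodes (as edge list)."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for u, v in combinations(range(n), 2):
        if rng.random() < 0.5:
            edges.append((nodes[u], nodes[v]))
    return nodes, edges
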