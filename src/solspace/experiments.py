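"""Benchmark protocols: input-ordering bias runs and the nc x cs sweep.

The ring of cliques with a central node admits a small set of reference
solutions constructible by definition: ``P1..P_nc`` assign the centre to one
clique each, and ``P_singleton`` isolates it in its own community.  Graph
automorphisms map any ``P_i`` to any ``P_j``, so an order-invariant unbiased
algorithm should distribute its runs uniformly over the symmetric
references.  The bias experiment runs an algorithm a fixed number of times
under (a) the graph's frozen storage order and (b) a fresh permutation per
run, tallies the matched reference of each run, and compares the two tables:
a chi-square goodness-of-fit against uniformity over the symmetric
references per condition, and a chi-square homogeneity test between the
conditions.  These runs deliberately bypass the Bayesian stopping rule —
the experiment characterises the algorithm, not the posterior.

The sweep applies the full explore-and-classify pipeline over a grid of
ring-of-cliques sizes and reports the label per cell and the prevalent
(modal) label per algorithm.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .explorer import AlgorithmAdapter, ExplorationConfig, explore, trial_seeds
from .graphs import CENTRE, Graph, RingOfCliquesSpec, permute, ring_of_cliques
from .partitions import Partition
from .taxonomy import SpaceClassification, classify

__all__ = [
    "reference_partitions",
    "BiasExperimentResult",
    "bias_experiment",
    "SweepResult",
    "sweep",
]

OTHER = "OTHER"
SINGLETON = "P_singleton"


def reference_partitions(spec: RingOfCliquesSpec) -> dict[str, Partition]:
    """The analytically constructed reference solutions of an RC / RC+C graph.

    For a plain ring of cliques: one reference, ``P_cliques`` (each clique a
    community).  With a central node: ``P1..P_nc`` (centre joined to clique
    i) plus ``P_singleton`` (centre alone).
    """
    base = {
        node: i for i in range(spec.n_cliques) for node in spec.clique_members(i)
    }
    if not spec.central_node:
        return {"P_cliques": Partition(base)}
    refs: dict[str, Partition] = {}
    for i in range(spec.n_cliques):
        a = dict(base)
        a[CENTRE] = i
        refs[f"P{i + 1}"] = Partition(a)
    a = dict(base)
    a[CENTRE] = spec.n_cliques
    refs[SINGLETON] = Partition(a)
    return refs


@dataclass
class BiasExperimentResult:
    """Fixed-order vs permuted-order run tallies for one algorithm."""

    algorithm: str
    spec: RingOfCliquesSpec
    n_runs: int
    categories: list[str]  # P1..P_nc, P_singleton (if central), OTHER
    fixed_counts: dict[str, int]
    permuted_counts: dict[str, int]
    # chi-square GOF vs uniform over the symmetric references, per condition
    fixed_gof: tuple[float, int, float]  # (statistic, df, p-value)
    permuted_gof: tuple[float, int, float]
    # chi-square homogeneity between the two condition tables
    homogeneity: tuple[float, int, float]
    alpha: float
    multiple_solutions: bool  # >1 distinct outcome under fixed order
    singleton_produced: bool  # the isolated-centre reference was ever matched

    @property
    def indistinguishable(self) -> bool:
        """Fixed and permuted tables statistically indistinguishable at alpha."""
        return self.homogeneity[2] > self.alpha

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "spec": {
                "n_cliques": self.spec.n_cliques,
                "clique_size": self.spec.clique_size,
                "central_node": self.spec.central_node,
            },
            "n_runs": self.n_runs,
            "categories": self.categories,
            "fixed_counts": self.fixed_counts,
            "permuted_counts": self.permuted_counts,
            "fixed_gof": list(self.fixed_gof),
            "permuted_gof": list(self.permuted_gof),
            "homogeneity": list(self.homogeneity),
            "alpha": self.alpha,
            "indistinguishable": self.indistinguishable,
            "multiple_solutions": self.multiple_solutions,
            "singleton_produced": self.singleton_produced,
        }


def _gof_uniform(counts: Sequence[int]) -> tuple[float, int, float]:
    """Chi-square goodness of fit against the uniform distribution."""
    c = np.asarray(counts, dtype=float)
    if c.sum() == 0:
        return (math.nan, len(c) - 1, math.nan)
    stat, p = stats.chisquare(c)
    return (float(stat), len(c) - 1, float(p))


def _homogeneity(a: Sequence[int], b: Sequence[int]) -> tuple[float, int, float]:
    """Chi-square homogeneity between two count tables over the same categories.

    All-zero categories are dropped; a degenerate table (fewer than two
    informative categories) yields p = 1 when the tables are identical and
    p = 0 otherwise.
    """
    table = np.array([a, b], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        same = bool(np.array_equal(table[0], table[1]))
        return (0.0 if same else math.inf, 0, 1.0 if same else 0.0)
    stat, p, df, _ = stats.chi2_contingency(table)
    return (float(stat), int(df), float(p))


def bias_experiment(
    algo: AlgorithmAdapter,
    spec: RingOfCliquesSpec,
    n_runs: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> BiasExperimentResult:
    """Run ``algo`` ``n_runs`` times under fixed and permuted input ordering.

    Each run is matched exactly (canonical set-partition equality) to one
    reference category; unmatched runs fall into ``OTHER``.  In both
    conditions the algorithm receives a fresh per-run seed; only the
    permuted condition additionally reorders the graph storage per run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    g = ring_of_cliques(spec)
    refs = reference_partitions(spec)
    ref_by_canon = {p.canonical_form(): name for name, p in refs.items()}
    symmetric = [f"P{i + 1}" for i in range(spec.n_cliques)] if spec.central_node else ["P_cliques"]
    categories = list(refs) + [OTHER]

    def run_condition(permuted: bool, offset: int) -> tuple[Counter, set]:
        counts: Counter = Counter({c: 0 for c in categories})
        outcomes = set()
        for r in range(n_runs):
            perm_seed, algo_seed = trial_seeds(seed + offset, r)
            g_r = permute(g, perm_seed) if permuted else g
            p = algo(g_r, algo_seed)
            cf = p.canonical_form()
            counts[ref_by_canon.get(cf, OTHER)] += 1
            outcomes.add(cf)
        return counts, outcomes

    fixed_counts, fixed_outcomes = run_condition(False, offset=0)
    permuted_counts, _ = run_condition(True, offset=1)

    return BiasExperimentResult(
        algorithm=algo.name,
        spec=spec,
        n_runs=n_runs,
        categories=categories,
        fixed_counts=dict(fixed_counts),
        permuted_counts=dict(permuted_counts),
        fixed_gof=_gof_uniform([fixed_counts[c] for c in symmetric]),
        permuted_gof=_gof_uniform([permuted_counts[c] for c in symmetric]),
        homogeneity=_homogeneity(
            [fixed_counts[c] for c in categories],
            [permuted_counts[c] for c in categories],
        ),
        alpha=alpha,
        multiple_solutions=len(fixed_outcomes) > 1,
        singleton_produced=spec.central_node
        and (fixed_counts[SINGLETON] + permuted_counts[SINGLETON] > 0),
    )


@dataclass
class SweepResult:
    """Solution-space labels over a (nc, cs) grid, per algorithm."""

    nc_values: list[int]
    cs_values: list[int]
    labels: dict[str, dict[tuple[int, int], str]]  # algo -> (nc, cs) -> label
    failures: dict[str, dict[tuple[int, int], str]] = field(default_factory=dict)

    def prevalent(self) -> dict[str, str]:
        """Modal label per algorithm over the completed cells."""
        out = {}
        for algo, cells in self.labels.items():
            if cells:
                out[algo] = Counter(cells.values()).most_common(1)[0][0]
        return out

    def to_dict(self) -> dict:
        return {
            "nc_values": self.nc_values,
            "cs_values": self.cs_values,
            "labels": {
                algo: {f"{nc}x{cs}": lab for (nc, cs), lab in cells.items()}
                for algo, cells in self.labels.items()
            },
            "failures": {
                algo: {f"{nc}x{cs}": msg for (nc, cs), msg in cells.items()}
                for algo, cells in self.failures.items()
            },
            "prevalent": self.prevalent(),
        }


def sweep(
    algos: Sequence[AlgorithmAdapter],
    nc_values: Sequence[int],
    cs_values: Sequence[int],
    cfg: Optional[ExplorationConfig] = None,
    central_node: bool = True,
    treat_degenerate_as_invalid: bool = True,
    sparse_ratio: float = 0.8,
) -> SweepResult:
    """Explore and classify every (algorithm, nc, cs) cell; failures are
    recorded per cell and do not abort the sweep."""
    if not nc_values or not cs_values:
        raise ValueError("nc_values and cs_values must be nonempty")
    cfg = cfg or ExplorationConfig()
    labels: dict[str, dict[tuple[int, int], str]] = {}
    failures: dict[str, dict[tuple[int, int], str]] = {}
    for algo in algos:
        labels[algo.name] = {}
        failures[algo.name] = {}
        for nc in nc_values:
            for cs in cs_values:
                g = ring_of_cliques(RingOfCliquesSpec(nc, cs, central_node=central_node))
                try:
                    result = explore(g, algo, cfg)
                    cls: SpaceClassification = classify(
                        result,
                        treat_degenerate_as_invalid=treat_degenerate_as_invalid,
                        sparse_ratio=sparse_ratio,
                    )
                    labels[algo.name][(nc, cs)] = cls.label
                except Exception as exc:
                    failures[algo.name][(nc, cs)] = str(exc)
    return SweepResult(list(nc_values), list(cs_values), labels, failures)
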