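"""The exploration loop: repeated detection trials with a Bayesian stopping rule.

Each trial (1) draws an information-preserving permutation of the input
graph, (2) runs the community-detection adapter on it, (3) matches the
returned partition against the unique solutions seen so far by exact
canonical-form equality (semantically the NMI = 1 criterion), and (4)
updates the Dirichlet–Multinomial model.  The loop stops on stabilisation,
separation, or after ``t_max`` trials.

Adapters wrap the standard igraph implementations of six widely used
algorithms — Edge Betweenness (eb), Louvain (lv), Leiden (ld), Label
Propagation (lp), Infomap (im) and Walktrap (wt) — behind a uniform
``adapter(graph, seed) -> Partition`` contract.  The adapter receives the
graph's *storage order* verbatim (nodes and edges are handed to igraph in
list order, with no hint of any original ordering), which is what makes
input-ordering bias observable.  Per-trial seeds are derived from the master
seed by a counter-based splitting scheme, so every trial is individually
reproducible and trials are mutually independent.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Optional

import igraph as ig
import numpy as np

from . import bayes
from .bayes import NEW, ConvergenceStatus, DirichletModel
from .graphs import Graph, permute
from .partitions import Partition, ValidityReport, validate

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmAdapter",
    "ExplorationConfig",
    "ExplorationError",
    "ExplorationResult",
    "TrialRecord",
    "builtin_adapter",
    "explore",
    "trial_seeds",
    "BUILTIN_ALGORITHMS",
]


class ExplorationError(RuntimeError):
    """An adapter failed or broke its contract during a trial."""


@dataclass
class AlgorithmAdapter:
    """A community-detection algorithm behind a uniform calling contract.

    ``fn(graph, seed)`` must return a :class:`Partition` covering exactly
    the graph's nodes.  ``stochastic`` and ``can_singleton`` are descriptive
    capability flags (does the algorithm vary across seeded runs on a fixed
    input; can it place a single node in its own community).
    """

    name: str
    fn: Callable[[Graph, int], Partition]
    params: dict = field(default_factory=dict)
    stochastic: bool = True
    can_singleton: bool = True

    def __call__(self, g: Graph, seed: int) -> Partition:
        p = self.fn(g, seed)
        if p.node_set != frozenset(g.nodes):
            raise ExplorationError(
                f"adapter {self.name!r} returned a partition on a different node set"
            )
        return p


# -- igraph-backed builtin adapters ---------------------------------------

#: Above this node count Edge Betweenness logs a runtime warning: the
#: algorithm recomputes all betweenness scores after every edge removal and
#: becomes impractical on large graphs.
EB_NODE_GUARD = 1000


def _to_igraph(g: Graph) -> ig.Graph:
    """Convert preserving storage order of nodes and edges exactly."""
    index = {n: i for i, n in enumerate(g.nodes)}
    edges = [(index[u], index[v]) for u, v, _ in g.edges]
    igg = ig.Graph(n=g.n_v, edges=edges, directed=False)
    igg.es["weight"] = [w for _, _, w in g.edges]
    return igg


def _membership_to_partition(g: Graph, membership) -> Partition:
    return Partition({node: int(label) for node, label in zip(g.nodes, membership)})


def _run_eb(g: Graph, seed: int, params: dict) -> Partition:
    if g.n_v > EB_NODE_GUARD:
        logger.warning(
            "edge betweenness on %d nodes exceeds the practicality guard (%d); this may take very long",
            g.n_v,
            EB_NODE_GUARD,
        )
    igg = _to_igraph(g)
    random.seed(seed)
    dendro = igg.community_edge_betweenness(weights="weight")
    return _membership_to_partition(g, _cut(dendro, params))


def _cut(dendro, params: dict):
    """Cut a dendrogram: by explicit community count or the library's optimal-modularity cut."""
    n = params.get("n_communities")
    clustering = dendro.as_clustering(n=n) if n else dendro.as_clustering()
    return clustering.membership


def _run_lv(g: Graph, seed: int, params: dict) -> Partition:
    igg = _to_igraph(g)
    random.seed(seed)
    clustering = igg.community_multilevel(
        weights="weight", resolution=params.get("resolution", 1.0)
    )
    return _membership_to_partition(g, clustering.membership)


def _run_ld(g: Graph, seed: int, params: dict) -> Partition:
    import leidenalg

    igg = _to_igraph(g)
    objective = params.get("objective", "modularity")
    kwargs = {"weights": igg.es["weight"], "seed": int(seed) % (2**31)}
    if objective == "modularity":
        ptype = leidenalg.ModularityVertexPartition
    elif objective == "cpm":
        ptype = leidenalg.CPMVertexPartition
        kwargs["resolution_parameter"] = params.get("resolution", 1.0)
    else:
        raise ValueError(f"unknown Leiden objective {objective!r}")
    part = leidenalg.find_partition(igg, ptype, **kwargs)
    return _membership_to_partition(g, part.membership)


def _run_lp(g: Graph, seed: int, params: dict) -> Partition:
    igg = _to_igraph(g)
    random.seed(seed)
    clustering = igg.community_label_propagation(weights="weight")
    return _membership_to_partition(g, clustering.membership)


def _run_im(g: Graph, seed: int, params: dict) -> Partition:
    igg = _to_igraph(g)
    random.seed(seed)
    clustering = igg.community_infomap(
        edge_weights="weight", trials=params.get("trials", 10)
    )
    return _membership_to_partition(g, clustering.membership)


def _run_wt(g: Graph, seed: int, params: dict) -> Partition:
    igg = _to_igraph(g)
    random.seed(seed)
    dendro = igg.community_walktrap(weights="weight", steps=params.get("steps", 4))
    return _membership_to_partition(g, _cut(dendro, params))


BUILTIN_ALGORITHMS = {
    "eb": (_run_eb, {"stochastic": False, "can_singleton": False}),
    "lv": (_run_lv, {"stochastic": True, "can_singleton": False}),
    "ld": (_run_ld, {"stochastic": True, "can_singleton": True}),
    "lp": (_run_lp, {"stochastic": True, "can_singleton": False}),
    "im": (_run_im, {"stochastic": True, "can_singleton": True}),
    "wt": (_run_wt, {"stochastic": False, "can_singleton": False}),
}


def builtin_adapter(name: str, params: Optional[dict] = None) -> AlgorithmAdapter:
    """Adapter for one of the six built-in algorithms (``eb lv ld lp im wt``).

    ``params`` passes algorithm-specific knobs through to the library:
    ``resolution`` (lv, ld), ``objective`` (ld: ``modularity``/``cpm``),
    ``steps`` (wt random-walk length), ``trials`` (im), ``n_communities``
    (explicit dendrogram cut for eb/wt).  Defaults are the library defaults.
    """
    key = name.lower()
    if key not in BUILTIN_ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {name!r}; available: {', '.join(sorted(BUILTIN_ALGORITHMS))}"
        )
    fn, flags = BUILTIN_ALGORITHMS[key]
    p = dict(params or {})
    return AlgorithmAdapter(
        name=key,
        fn=lambda g, seed, _fn=fn, _p=p: _fn(g, seed, _p),
        params=p,
        **flags,
    )


# -- exploration -----------------------------------------------------------


@dataclass
class ExplorationConfig:
    """Parameters of the exploration loop.

    ``delta`` is the credible-interval width tolerance of the stabilisation
    rule and ``t_max`` the trial budget (defaults 0.1 and 50); ``gamma0``
    and ``level`` parameterise the Dirichlet model; ``t_min`` guards against
    premature stabilisation; ``permute_inputs=False`` disables the per-trial
    permutation (used to expose input-ordering bias); ``validity_policy``
    is ``count_all`` (invalid partitions are counted in the model and
    filtered at classification time) or ``drop_invalid``.
    """

    delta: float = 0.1
    t_max: int = 50
    gamma0: float = 1.0
    level: float = 0.95
    seed: int = 0
    t_min: int = 10
    permute_inputs: bool = True
    validity_policy: str = "count_all"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.t_max < 1:
            raise ValueError("t_max must be at least 1")
        if self.validity_policy not in ("count_all", "drop_invalid"):
            raise ValueError("validity_policy must be 'count_all' or 'drop_invalid'")

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "t_max": self.t_max,
            "gamma0": self.gamma0,
            "level": self.level,
            "seed": self.seed,
            "t_min": self.t_min,
            "permute_inputs": self.permute_inputs,
            "validity_policy": self.validity_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExplorationConfig":
        return cls(**d)


def trial_seeds(master_seed: int, trial: int) -> tuple[int, int]:
    """Counter-split ``master_seed`` into (permutation seed, algorithm seed) for one trial."""
    state = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(trial),)).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


@dataclass
class TrialRecord:
    trial: int
    solution_index: Optional[int]
    novel: bool
    dropped_invalid: bool
    p_hat: list[float]
    intervals: list[list[float]]

    def to_dict(self) -> dict:
        return {
            "trial": self.trial,
            "solution_index": self.solution_index,
            "novel": self.novel,
            "dropped_invalid": self.dropped_invalid,
            "p_hat": self.p_hat,
            "intervals": self.intervals,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(
            trial=d["trial"],
            solution_index=d["solution_index"],
            novel=d["novel"],
            dropped_invalid=d.get("dropped_invalid", False),
            p_hat=list(d["p_hat"]),
            intervals=[list(iv) for iv in d["intervals"]],
        )


@dataclass
class ExplorationResult:
    """Everything one exploration produced.

    ``solutions`` are the unique partitions in discovery order; ``model``
    the final posterior (``model.k == len(solutions)``); ``validity`` one
    report per solution; ``trace`` one record per executed trial;
    ``termination`` the final convergence status.
    """

    algorithm: str
    config: ExplorationConfig
    solutions: list[Partition]
    model: DirichletModel
    validity: list[ValidityReport]
    trace: list[TrialRecord]
    termination: ConvergenceStatus

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    @property
    def trials(self) -> int:
        return len(self.trace)

    def n_valid(self, treat_degenerate_as_invalid: bool = True) -> int:
        return sum(
            1
            for v in self.validity
            if v.is_valid and not (treat_degenerate_as_invalid and v.is_degenerate)
        )

    def to_dict(self) -> dict:
        if self.model.t >= 1:
            p_hat, intervals = self.model.posterior()
        else:  # every trial dropped as invalid: no posterior to report
            p_hat, intervals = np.empty(0), np.empty((0, 2))
        return {
            "algorithm": self.algorithm,
            "config": self.config.to_dict(),
            "solutions": [p.canonical_labels() for p in self.solutions],
            "model": self.model.to_dict(),
            "p_hat": p_hat.tolist(),
            "intervals": intervals.tolist(),
            "validity": [v.to_dict() for v in self.validity],
            "trace": [r.to_dict() for r in self.trace],
            "termination": {
                "converged": self.termination.converged,
                "cause": self.termination.cause,
                "dominant_index": self.termination.dominant_index,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExplorationResult":
        term = d["termination"]
        return cls(
            algorithm=d["algorithm"],
            config=ExplorationConfig.from_dict(d["config"]),
            solutions=[Partition(s) for s in d["solutions"]],
            model=DirichletModel.from_dict(d["model"]),
            validity=[ValidityReport.from_dict(v) for v in d["validity"]],
            trace=[TrialRecord.from_dict(r) for r in d["trace"]],
            termination=ConvergenceStatus(
                converged=term["converged"],
                cause=term["cause"],
                dominant_index=term["dominant_index"],
            ),
        )


def explore(g: Graph, algo: AlgorithmAdapter, cfg: Optional[ExplorationConfig] = None) -> ExplorationResult:
    """Explore the solution space of ``algo`` on ``g``.

    Runs sequential trials — permute, detect, match, update — until the
    Dirichlet model stabilises or separates, or the trial budget ``t_max``
    is exhausted.  Fully reproducible given ``cfg.seed`` and an adapter that
    is deterministic given its seed.
    """
    cfg = cfg or ExplorationConfig()
    model = DirichletModel(gamma0=cfg.gamma0, level=cfg.level)
    solutions: list[Partition] = []
    validity: list[ValidityReport] = []
    canon_index: dict = {}
    trace: list[TrialRecord] = []
    status = ConvergenceStatus(False, bayes.RUNNING)

    for t in range(1, cfg.t_max + 1):
        perm_seed, algo_seed = trial_seeds(cfg.seed, t)
        g_t = permute(g, perm_seed) if cfg.permute_inputs else g
        try:
            p_t = algo(g_t, algo_seed)
        except ExplorationError:
            raise
        except Exception as exc:  # surface with the trial index
            raise ExplorationError(f"adapter {algo.name!r} failed at trial {t}: {exc}") from exc

        report = validate(g, p_t)
        if cfg.validity_policy == "drop_invalid" and not report.is_valid:
            # observed but excluded from the model; the trial still counts in the trace
            trace.append(TrialRecord(t, None, False, True, [], []))
            if t >= cfg.t_max:
                status = ConvergenceStatus(False, bayes.MAX_TRIALS)
                break
            continue

        cf = p_t.canonical_form()
        if cf in canon_index:
            idx = canon_index[cf]
            novel = False
            model.observe(idx)
        else:
            idx = len(solutions)
            canon_index[cf] = idx
            solutions.append(p_t)
            validity.append(report)
            novel = True
            model.observe(NEW)

        status = model.check_convergence(cfg.delta, cfg.t_max, cfg.t_min)
        p_hat, intervals = model.posterior()
        trace.append(
            TrialRecord(t, idx, novel, False, p_hat.tolist(), intervals.tolist())
        )
        if status.converged or status.cause == bayes.MAX_TRIALS:
            break

    return ExplorationResult(
        algorithm=algo.name,
        config=cfg,
        solutions=solutions,
        model=model,
        validity=validity,
        trace=trace,
        termination=status,
    )
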