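"""Shared fixtures: benchmark graphs, reference partitions and mock adapters.

The mock adapters engineer the four canonical solution-space shapes without
any real detection algorithm: a constant adapter (one solution), a uniform
sampler over the four symmetric references (comparable solutions), an
always-novel adapter (a fresh solution every trial) and an all-invalid
adapter (every solution violates the community requirements).
"""

from __future__ import annotations

import numpy as np
import pytest

from solspace import (
    AlgorithmAdapter,
    Partition,
    RingOfCliquesSpec,
    reference_partitions,
    ring_of_cliques,
)


@pytest.fixture(scope="session")
def rcc_spec():
    return RingOfCliquesSpec(n_cliques=4, clique_size=5, central_node=True)


@pytest.fixture(scope="session")
def rcc_graph(rcc_spec):
    return ring_of_cliques(rcc_spec)


@pytest.fixture(scope="session")
def rcc_refs(rcc_spec):
    """P1..P4 (centre joined to each clique) and P_singleton."""
    return reference_partitions(rcc_spec)


@pytest.fixture
def triangle():
    from solspace import Graph

    return Graph(["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")])


# -- mock adapters ---------------------------------------------------------


@pytest.fixture
def constant_adapter(rcc_refs):
    p1 = rcc_refs["P1"]
    return AlgorithmAdapter(
        name="mock-constant", fn=lambda g, seed: p1, stochastic=False
    )


@pytest.fixture
def uniform4_adapter(rcc_refs):
    choices = [rcc_refs[f"P{i}"] for i in range(1, 5)]
    return AlgorithmAdapter(
        name="mock-uniform4",
        fn=lambda g, seed: choices[int(np.random.default_rng(seed).integers(4))],
    )


@pytest.fixture
def novel_adapter(rcc_spec):
    """A fresh, structurally valid partition at every call.

    Call ``i`` carves out the endpoints of the i-th clique-internal edge not
    touching the clique's gateway member, as a two-node community; the rest
    of the graph stays one connected community.
    """
    pairs = []
    for c in range(rcc_spec.n_cliques):
        members = rcc_spec.clique_members(c)[1:]  # skip the gateway node
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.append((members[a], members[b]))
    counter = {"i": 0}

    def fn(g, seed):
        u, v = pairs[counter["i"] % len(pairs)]
        counter["i"] += 1
        return Partition({n: (1 if n in (u, v) else 0) for n in g.nodes})

    return AlgorithmAdapter(name="mock-novel", fn=fn)


@pytest.fixture
def invalid_adapter():
    """Always the single all-encompassing community (structurally invalid)."""
    return AlgorithmAdapter(
        name="mock-invalid", fn=lambda g, seed: Partition({n: 0 for n in g.nodes})
    )
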