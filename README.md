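# solspace

Solution-space exploration for stochastic community detection.

Community detection algorithms (Louvain, Leiden, label propagation, Infomap,
Walktrap, edge betweenness, …) are routinely treated as if they returned
*the* partition of a network. In practice many of them are stochastic, and
most are sensitive to the storage order of nodes and edges — an artifact of
software, not of topology. A single run therefore samples one point from a
*solution space* 𝕊 = {P₁, …, P_nₛ} of distinct partitions, and interpreting
that one sample as ground truth can elevate a minority partition to apparent
representativeness. This package is for network analysts — in systems
biology, innovation studies, social network analysis — who need to know how
trustworthy a partition is before building conclusions on it.

## What it does

Given a graph `G` and an algorithm `𝒜`, `solspace` repeatedly runs `𝒜` on
*information-preserving permutations* of `G` (same nodes, edges and weights;
fresh storage order each trial, so order artifacts cannot hide). Each
returned partition `P_t` is matched against the solutions seen so far by
exact set-partition equality — semantically the NMI(P_t, P_j) = 1 criterion,
immune to floating error. The unique solutions are modelled sequentially
with a Dirichlet–Multinomial posterior

    p | c ~ Dirichlet(γ₀ + c₁, …, γ₀ + c_k)

whose marginal Beta distributions give each solution a probability estimate
p̂ᵢ with an equal-tailed credible interval [pᵢˡ, pᵢᵘ]. Exploration stops on:

- **stabilisation** — maxᵢ (pᵢᵘ − pᵢˡ) ≤ δ (all estimates precise enough),
- **separation** — ∃ i★ : p_{i★}ˡ > max_{j≠i★} pⱼᵘ (one solution dominant),
- or the trial budget `t_max`.

The explored space is then classified into one of five types: **Single**
(one stable partition), **Dominant** (one solution probabilistically
separated from the rest), **Multiple** (several comparable solutions),
**Sparse** (nearly every trial novel, nₛ ≈ t), or **Empty** (no valid
solution — everything returned was one big community, all singletons,
internally disconnected, or degenerate with more inter- than intra-community
edges). Finally a pairwise agreement matrix

    γ_uv = Σᵢ p̂ᵢ · χᵢ(u, v)

(χᵢ(u,v) = 1 iff u and v share a community in Pᵢ) summarises node stability:
the mean of a node's non-zero entries, γ̄ᵥ⁽⁺⁾, is near 1 for nodes that
always travel with the same companions and low for outliers whose
membership flips between solutions.

## Worked example

The benchmark is a ring of four 5-cliques plus a central hub connected once
to each clique (RC+C). The hub is a designed outlier: by symmetry there are
four equivalent solutions P₁–P₄ (hub absorbed into one clique each), so no
single partition deserves more than ≈ 1/4 posterior probability.

```python
from solspace import (RingOfCliquesSpec, ring_of_cliques, builtin_adapter,
                      explore, ExplorationConfig, classify, symmetry_note,
                      agreement_from_result, outlier_profiles)
from solspace.cli import render_report

g = ring_of_cliques(RingOfCliquesSpec(4, 5, central_node=True))
res = explore(g, builtin_adapter("wt"), ExplorationConfig(seed=7))
print(render_report(res, classify(res)))
print(symmetry_note(res, 4))
```

prints

```
Algorithm:        wt
Convergence:      max. trials
Trials:           50
Total solutions:  4
Valid solutions:  4
Type of solution space: Multiple
Solutions (p_hat [lower, upper]):
  P1: 0.259 [0.153, 0.383]
  P2: 0.296 [0.183, 0.423]
  P3: 0.185 [0.094, 0.298]
  P4: 0.259 [0.153, 0.383]
consistent with 4-fold symmetry: max p_hat=0.296 with interval [0.183, 0.423] containing 1/4=0.250
```

Walktrap — deterministic on a fixed input order, where it would report a
*Single* space and silently pick one clique for the hub — reveals a
*Multiple* space of four comparable symmetric solutions once the input order
is permuted per trial. The agreement profile pins down who is responsible:

```python
profs = {p.node: p for p in outlier_profiles(agreement_from_result(res))}
print(profs["centre"].gamma_bar_plus)   # 0.25  -> unstable outlier
print(profs["c0_n1"].mean_top_agreement)  # 1.0 -> always with its clique
```

The same pipeline is available from the shell:

```bash
solspace explore --generate rc+c:4,5 --algo wt --seed 7 --out runs/wt
solspace agreement --result runs/wt --threshold 0.5
solspace bias --algo lp --nc 4 --cs 5 --runs 1000 --seed 1 --out runs/bias
solspace sweep --algos lv,lp,wt --nc 2:8 --cs 3:6 --out runs/sweep
```

`explore` also reads real networks from edge-list CSV/TSV (`source,
target[, weight]`) or GraphML files.

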