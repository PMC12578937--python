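# Methods

## Model

One exploration treats a community-detection algorithm `𝒜` applied to a
graph `G` as a sampling process over an unknown, finite set of distinct
partitions. Trials are made exchangeable by double randomisation: the
algorithm's own stochasticity (each trial gets a fresh derived seed) plus an
independent information-preserving permutation of the graph's storage order
(node list uniformly permuted, edge list independently shuffled, endpoint
order of each edge flipped with probability ½). The permutation changes
nothing an order-invariant algorithm could observe; everything an
order-*sensitive* one does.

Unique solutions are the categories of a multinomial with unknown
probabilities **p**. With a symmetric Dirichlet prior of concentration `γ₀`
per category, the posterior after counts **c** is
`Dirichlet(γ₀ + c₁, …, γ₀ + c_k)`; marginals are
`Beta(γ₀ + cᵢ, (k−1)γ₀ + t − cᵢ)`. When a novel solution appears the
support grows by one and the symmetric prior is re-formed over the current
`k`; the state is a function of the counts alone, so observation order never
matters. This is deliberately *not* a Dirichlet process: no mass is
reserved for unseen solutions, which keeps the posterior interpretable as
"probabilities of the solutions actually on the table" and keeps the
stopping rules simple.

### Matching

Two partitions are the same solution iff they induce the same set partition
of the nodes. Matching uses a canonical form (sorted tuple of sorted
blocks, no hashing) rather than thresholding a floating-point NMI value;
the two criteria coincide exactly, since NMI = 1 holds precisely on
identical set partitions under every normalisation. NMI itself (arithmetic
normalisation by default; min/max/geometric available) is kept as a
diagnostic similarity, delegated to scikit-learn.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `delta` (δ) | 0.1 | stabilisation tolerance: max credible-interval width |
| `t_max` | 50 | trial budget |
| `gamma0` (γ₀) | 1.0 | prior count per solution (uniform/Laplace prior) |
| `level` | 0.95 | credible level of the equal-tailed Beta intervals |
| `t_min` | 10 | minimum trials before stabilisation may fire |
| `sparse_ratio` | 0.8 | novelty fraction at which a space is called Sparse |
| outlier threshold | 0.5 | γ̄ᵥ⁽⁺⁾ below which a node is flagged |

δ = 0.1 and `t_max` = 50 are the working defaults for the benchmark
experiments; all are configurable per call and echoed into every output for
provenance. `γ₀` and the credible level are genuinely open choices: γ₀ = 1
is the weakly informative uniform prior, 0.95 the conventional level. Only
the NMI-equals-one predicate (prior-free) enters the matching step, so these
choices affect interval widths and stopping times, not which solutions are
found.

### The k = 1 edge case

With a single known solution the posterior over its probability is a point
mass at 1 (the model conditions on the observed support), so the
stabilisation width is 0 and the rule would fire after one trial. `t_min`
(default 10) makes a Single verdict mean "one solution found *and* given a
real chance to be contradicted". It applies to the stabilisation predicate
generally; separation needs k ≥ 2 and non-trivial counts, so it needs no
guard.

### Stopping-rule evaluation order

Stabilisation is checked before separation at every trial; if both hold the
cause is recorded as stabilisation. `MAX_TRIALS` is reported only when
neither fired within the budget.

## Taxonomy decisions

The label cascade is: **Empty** (no valid solution) → **Single** (exactly
one valid solution, stabilised) → **Dominant** (separation with a valid
dominant solution) → **Sparse** → **Multiple**. Two boundaries required a
decision:

- **Sparse is a property of novelty, not of the termination cause.** A space
  in which nearly every trial is novel can *stabilise*: with `k ≈ t`
  categories each probability is small and its interval narrow, so the
  width criterion is met even though the space is clearly sparse. Sparse is
  therefore diagnosed by the novelty ratio `n_valid / t ≥ sparse_ratio`
  regardless of whether the run stopped by stabilisation or by budget
  (separation, which cannot coexist with near-uniform novelty, still takes
  precedence). The Multiple/Sparse boundary is inherently grey;
  `sparse_ratio` is configurable and always echoed in the rationale.
- **Degenerate solutions** (more inter- than intra-community edges,
  contradicting the definition of a community) stay in the model's counts
  but by default count as invalid at classification time, so a space whose
  every solution is degenerate is Empty. `treat_degenerate_as_invalid=False`
  restores the lenient reading. The inter/intra comparison is global and
  unweighted by default (a weighted variant is a switch), since degeneracy
  is about edge placement, not edge strength.
- Multiple's two textbook conditions (overlapping intervals; max lower
  bound < ½) can in principle disagree; both are evaluated and reported in
  the rationale, overlap decides, and a disagreement is flagged.

## Benchmark generators

- **Ring of cliques (RC)**: `nc` complete graphs of size `cs` joined in one
  cycle by single edges between consecutive cliques. For `nc = 2` the cycle
  degenerates to a single bridging edge (a two-edge "cycle" would duplicate
  an undirected edge).
- **RC+C**: RC plus a central hub connected once to each clique, to its
  lowest-index member. The choice of member is immaterial by clique
  symmetry; fixing it keeps the generator deterministic. Node names
  (`c{i}_n{j}`, `centre`) make agreement profiles readable. Ring edges join
  the `n0` members of consecutive cliques; any consistent choice preserves
  the `nc`-fold symmetry of the hub's attachment.
- **Erdős–Rényi G(n, p)**: the null model on which any detected "structure"
  is noise — the canonical producer of Sparse spaces.

Generators emit weight 1.0 on every edge; all downstream code accepts
arbitrary positive weights (real collaboration networks are weighted).

What the synthetic benchmarks emulate — and what they do not: RC+C isolates
*one* mechanism (a symmetric outlier with an exactly known solution set) in
an otherwise trivially modular graph. Real networks have fuzzy community
boundaries, heavy-tailed degrees and weights, and solution spaces whose
members differ in many nodes at once. Tests passing on RC+C therefore
certify the machinery (permutation, matching, posterior, classification,
agreement arithmetic), not the behaviour of any algorithm on real data.

## Algorithm adapters

The six built-ins delegate to python-igraph (Leiden via leidenalg, which
exposes a seed): edge betweenness `eb`, Louvain `lv`, Leiden `ld`, label
propagation `lp`, Infomap `im`, Walktrap `wt`. Library defaults are used
throughout (Leiden optimises modularity by default here; `objective="cpm"`
with a resolution is available). Dendrogram-producing algorithms (eb, wt)
are cut at the library's optimal-modularity cut unless an explicit
community count is requested — no unique cut rule exists, so the choice is
surfaced as a parameter. Capability flags and any class-level claims about
specific algorithms (e.g. whether Leiden will isolate a hub) depend on the
backing library's version and objective; the test suite asserts only
behaviours that are stable contracts (label propagation cannot keep a label
in the minority everywhere, hence never isolates the RC+C hub; Walktrap is
deterministic on a fixed order).

Per-trial seeds come from a counter-based split
(`SeedSequence(master, spawn_key=(trial,))`) giving one permutation seed
and one algorithm seed per trial — independent streams, each trial
individually replayable.

## Agreement and outliers

`γ_uv = Σᵢ p̂ᵢ χᵢ(u, v)` is computed as an exact finite sum, so zero entries
are exactly zero and the "exclude never-co-occurring pairs" rule needs no
tolerance. Per node, two scalar views are emitted side by side:
`gamma_bar_plus`, the mean over all non-zero off-diagonal partners, and
`mean_top_agreement`, the mean over the partners attaining the node's
maximum agreement. The two coincide for pure outliers (the RC+C hub scores
0.25 either way) and differ for stable nodes with weak cross-links (a
clique node's 1.0-entries versus its 0.25 link to the hub); reporting both
avoids baking either reading into the statistic. A node with no non-zero
partner gets NaN means and an outlier flag rather than an exception. The
outlier threshold (0.5) is reported alongside every profile, never silently
applied.

## Bias experiment

Fixed-order versus permuted-order runs at a fixed run count deliberately
bypass the stopping rule — the experiment characterises the algorithm, not
the posterior. Matching to the analytically constructed references
(P₁..P_nc, the singleton-hub solution, OTHER) is exact. "Statistically
indistinguishable" is operationalised as a chi-square homogeneity test
between the two condition tables at α = 0.01 (all-zero categories dropped);
per-condition uniformity over the symmetric references is a chi-square
goodness-of-fit. Both statistics, their degrees of freedom and p-values are
part of the result object.

## Numerical choices and problem sizes

Beta interval endpoints come from `scipy.stats.beta.ppf`; the test suite
checks them to 1e-8 against an independent quantile oracle (root-finding on
a numerically integrated density). Posterior means are exact rational
arithmetic in floating point (closed form). Probabilities passed to the
agreement matrix must sum to 1 within 1e-9.

Default problem sizes keep the full test suite and the acceptance script in
the seconds-to-a-couple-of-minutes range: RC+C(4, 5) (21 nodes) for all
benchmark work, 1000 runs for the frequency experiment, 200–300 runs for
bias signatures, 1000 replicates for interval coverage. The nc × cs sweep
is exercised on reduced grids in tests; the full 2–25 × 3–8 grid runs
through the same code path via the CLI when wanted.

## Known limitations

- Runtime scales linearly in trials × algorithm cost; edge betweenness is
  guarded (warning above 1000 nodes) but not forbidden.
- The posterior is over *observed* solutions only; it cannot state the
  probability that unseen solutions exist.
- Consensus construction across solutions and automatic graph-symmetry
  detection are out of scope (`symmetry_note` takes the symmetry count from
  the caller).
- Overlapping and hierarchical community structures are not first-class:
  dendrogram algorithms are consumed through a cut.
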