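# Methods

This note documents the models and procedures implemented in `modnetsim`, the
design choices made where the problem was genuinely open, and what the
simulation does and does not capture about real interaction-network sampling.

## Complete-network generator

The generator produces an undirected simple graph on `N` species partitioned
into modules. It composes five stages, each consuming one seeded random
stream, so a `(config, seed)` pair fully determines the network.

**Module sizes.** Sizes are i.i.d. Exponential(mean `M_av`) draws, rounded to
the nearest integer and truncated below at `min_module_size` (default 2 —
a module needs at least one possible interaction). Draws continue until the
cumulative sum reaches `N`; the final module is shrunk to close the sum
exactly, or merged into its predecessor if the remainder falls below the
minimum. The marginal law therefore has mean `M_av` up to the (small) rounding
and truncation shifts; the forced total introduces a mild edge effect in the
last module only. The sum-to-`N` rule is a package choice: only the
distribution and its mean are dictated by the sampling model being emulated.

**Module topologies.** Each module receives a template drawn from
`topology_mix` (default: uniform over random, scale-free, nested,
bipartite-nested — the four headline structures; "mixed" networks use exactly
this default). Modules too small for their drawn template (bipartite needs 2
per guild, tripartite 2 per level) fall back to `random`. The per-module
target degree is `min(k, size−1)`; modules smaller than `k+1` are built as
(near-)complete graphs, which pulls the whole-network mean degree a few
percent below `k` when `M_av` is small relative to `k`.

* *random*: `G(n, p)` with `p = k/(n−1)` — exact calibration in expectation.
* *scale_free*: preferential attachment with `m = round(k/2)` edges per new
  node from a complete seed on `m+1` nodes. Growth alone yields
  `m(n−m)+C(m,2)` edges, which undershoots the `n·k/2` budget at moderate
  module sizes, so edges with both endpoints drawn degree-proportionally are
  added until the budget is met. The top-up preserves the heavy tail (it is
  degree-reinforcing) while fixing the mean-degree calibration.
* *nested*: a perfectly nested threshold graph with an exponential degree
  distribution. Node ids double as hub ranks; per-node target degrees are
  `d_j = clip(round(s·r_j), 1, n−1)` with `r_j` descending Exponential(1)
  draws, and node `j` attaches to the `d_j` top-ranked hubs: edge `(i, j)`,
  `i < j`, iff `i < d_j`. For any two nodes `j1 < j2` every neighbor of `j2`
  is either a hub below `d_{j2} ≤ d_{j1}` or a high node attached above `j2`,
  hence also above `j1`: neighbor sets are totally ordered by inclusion
  (checked exhaustively in the tests). The scale `s` is found by bisection on
  the monotone realized edge count `Σ_j min(d_j, j)` so the module lands on
  `n·k/2` edges. The exponential degree law, rather than a deterministic
  staircase, is what makes nested modules behave as observed-network theory
  expects: most species have few partners, all of them shared hubs, so
  neighbor draws collide heavily.
* *bipartite nested / random*: two guilds of sizes `⌈n/2⌉, ⌊n/2⌋`, cross-guild
  edges only. The nested variant applies the same scaled-exponential hub rule
  across guilds; the random variant draws Bernoulli cross edges with the
  probability set by the `n·k/2` budget. Degree distributions decay
  exponentially below the structural saturation point: the top hubs of any
  finite nested guild necessarily connect to the entire opposite guild,
  piling mass at degree ≈ guild size.
* *tripartite nested / random*: three levels as equal as possible, edges
  between adjacent levels only, each block built by the corresponding
  bipartite rule. Each block carries an edge budget of `n·k/4` so the module
  total is `n·k/2` and the realized mean degree matches `k`; budgeting blocks
  at a per-block degree of `k/2` instead would leave the module mean near
  `2k/3`, which is why the edge-budget formulation was chosen.

**Rewiring.** Two stages, local then global, each one pass over a snapshot of
the (sorted) edge list. An edge is selected with probability `p_local`
(within-module stage) or `p_rew` (global stage); one endpoint is chosen
uniformly and reattached to a uniform node of the moved endpoint's module
(local) or of the whole network (global). Moves creating self-loops or
duplicate edges are rejected and the edge kept, so edge counts are conserved
exactly and the realized move rate is `p ×` (acceptance fraction). Global
rewiring is the only source of inter-module links; at `p_rew = 0` the
adjacency matrix is exactly block-diagonal. Defaults `p_local = p_rew = 0.1`
perturb the templates enough to remove their algorithmic signature while
preserving module identity.

**Abundances.** When a design samples by abundance, each module independently
receives i.i.d. per-node draws from one family — Exponential(rate, default 1),
Fisher log-series (`P(n) ∝ x^n/n`, default `x = 0.99`, sampled through
`scipy.stats.logser`), or lognormal (default `μ=0, σ=1`) — shuffled over the
module's nodes by a uniform permutation. Abundance is therefore structurally
uncorrelated with degree; defaults are the conventional choices of
species-abundance modelling and are exposed in the sampler config.

## Sampling model

`m` anchor-selection attempts are drawn **with replacement** from the scheme's
probability vector; repeats are discarded, so the distinct anchor count
follows the occupancy law `N(1−(1−p_i-mix)^m)` and falls below `m`. Schemes:
uniform; degree-proportional; abundance-proportional; module-weighted with
uniform within-module probability (`P(node in module M) = w_M/(|M|·Σw)`).
When the module scheme is used without explicit weights, one Uniform(0,1)
weight per module is drawn per sampling run, emulating heterogeneous taxon
preference.

Each distinct anchor of degree `d` receives a neighbor-attempt budget:
`all → d`, `single → 1`, `max_count → nfn` (attempts, not guaranteed distinct
neighbors), `fraction → max(1, round_half_up(f·d))`. Attempts draw neighbors
with replacement, uniformly or with probability proportional to per-node
Exponential(1) weights drawn once per sampling run (a proxy for interaction
frequency or partner abundance); repeated draws are lost. The legacy numeric
encoding (`1` = all, `1.1` = single, integer `> 1` = max count, `< 1` =
fraction) is accepted by the config parser and mapped to the explicit modes.

The observed network contains the anchors, every neighbor actually drawn, and
exactly the anchor–neighbor edges realized during expansion. Anchor–anchor
true links survive only when drawn; links between two non-anchors never enter.
Anchors whose draws realize no neighbors (isolated species in the complete
network) remain as isolated observed nodes — they were observed — which
directly affects component counts.

A deliberate consequence of counting anchors in the observed network: the
small-budget size asymptote `m·nfn` carries an `O(m)` anchor correction
(`≈ m(1+nfn)` for `nfn` small), so the `m·nfn` limit is verified in a regime
where `nfn` is large in absolute terms yet still far below `k`
(`nfn = 10, k ≈ 300`), where the approximation genuinely holds to within 10%.

## Metrics and experiment layer

Components are computed on the observed graph as constructed (isolated
anchors count as singleton components); `RSLC` is the largest component's
share of observed nodes; observed degree counts sampled edges only, for
anchors and neighbors alike. Replicated experiments regenerate **one**
complete network per topology cell and resample it for all replicates,
isolating sampling variance from generation variance; abundances are drawn
once per network and held fixed across replicates. All replicate seeds are
spawned from a single base seed.

Design comparisons use all-pairs Tukey HSD (statsmodels) at `α = 0.05` with a
compact letter display computed from maximal cliques of the non-significance
graph. Degenerate inputs: identical constants across all groups trivially
share one letter; zero within-group variance with differing means raises an
error, as the studentized range is undefined there.

## Study regime and problem sizes

The packaged study regime is `N = 500`, `M_av = 25`, `k = 10`,
`p_local = p_rew = 0.1`, `m = 50`, `nfn = 5` (max count), five topology cells
× five designs (random, degree, abundance-exponential, abundance-lognormal,
module), 1,000 replicates per cell. The acceptance script runs this grid in
well under a minute; the test suite exercises the same grid once and otherwise
uses smaller networks (N = 60–200) and replicate counts chosen so Monte-Carlo
margins (2–4 standard errors) stay meaningful.

## What the simulation does and does not capture

The generator emulates modular interaction structure, heavy-tailed and nested
degree structure, species-abundance heterogeneity, and detection budgets. It
deliberately omits: weighted or signed interactions, interaction types and
multilayer structure, directed links, temporal/repeat-visit sampling,
detectability differences between interactions of the same species, and any
guarantee of global connectivity. Passing tests therefore show that *sampling
design × topology* biases of the modelled kind are reproduced — not that any
particular field system matches these topologies.

Known limitations: with one generated network per topology cell, cell means
inherit generator-realization variance of a few percent; nested-guild degree
distributions saturate at the guild size (structural, see above); modules
smaller than `k+1` cannot reach the target degree, biasing whole-network mean
degree slightly downward at small `M_av`; and the exponential-weight neighbor
scheme fixes one weight per node per run (per-pair weights would model
dyad-specific detectability, which is out of scope).
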