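"""Construction of complete modular networks.

The generator composes five stages: (1) module sizes drawn from an exponential
law with mean ``M_av`` (rounded, truncated below, forced to sum to ``N``);
(2) a topology label per module drawn from the configured mix; (3) a
deterministic-or-stochastic template per module (random, scale-free, nested,
bipartite/tripartite variants); (4) within-module rewiring with probability
``p_local``; (5) whole-network rewiring with probability ``p_rew`` which is
the only mechanism creating inter-module links.

Rewiring semantics: each edge is visited once (a snapshot of the edge list);
with the stage probability one uniformly chosen endpoint is reattached to a
uniformly chosen node from the candidate pool (the moved endpoint's module for
the local stage, all N nodes for the global stage). Moves that would create a
self-loop or a duplicate edge are rejected and the edge kept, so the edge
count is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import (
    DEFAULT_ABUNDANCE_PARAMS,
    GeneratorConfig,
    MIN_TOPOLOGY_SIZE,
    TOPOLOGIES,
)
from .errors import ConfigError
from .network import Edge, ModularNetwork, canonical_edge

__all__ = [
    "ModuleSizeDraw",
    "draw_module_sizes",
    "build_module",
    "rewire_local",
    "rewire_global",
    "generate_network",
    "assign_abundances",
]


@dataclass
class ModuleSizeDraw:
    """A realized partition of N nodes into module sizes."""

    sizes: list[int]

    def __post_init__(self) -> None:
        self.sizes = [int(s) for s in self.sizes]

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    @property
    def total(self) -> int:
        return sum(self.sizes)

    @property
    def mean_size(self) -> float:
        return self.total / self.n_modules


def draw_module_sizes(
    N: int,
    M_av: float,
    min_module_size: int = 2,
    rng: np.random.Generator | None = None,
) -> ModuleSizeDraw:
    """Draw module sizes summing exactly to ``N``.

    Sizes are i.i.d. Exponential(mean ``M_av``) draws, rounded to the nearest
    integer and truncated below at ``min_module_size``; draws continue until
    the cumulative sum reaches ``N`` and the last module is shrunk to close the
    total exactly (merged into the previous module if the remainder falls
    below ``min_module_size``).
    """
    if not (min_module_size <= M_av <= N):
        raise ConfigError("require min_module_size <= M_av <= N")
    rng = np.random.default_rng() if rng is None else rng
    sizes: list[int] = []
    total = 0
    while total < N:
        s = max(min_module_size, int(round(rng.exponential(M_av))))
        sizes.append(s)
        total += s
    excess = total - N
    if excess > 0:
        last = sizes[-1] - excess
        # a single module always spans all of N (N >= M_av >= min_module_size)
        if last >= min_module_size or len(sizes) == 1:
            sizes[-1] = last
        else:
            sizes.pop()
            sizes[-1] += last
    return ModuleSizeDraw(sizes=sizes)


# ---------------------------------------------------------------------------
# module templates
# ---------------------------------------------------------------------------


def _target_edges(size: int, k: float, denom: int = 2) -> int:
    """Edge budget ``round(size*k/denom)`` capped by the complete graph."""
    return min(int(round(size * k / denom)), size * (size - 1) // 2)


def _er_edges(size: int, k: float, rng: np.random.Generator) -> set[Edge]:
    p = min(1.0, k / (size - 1))
    iu, ju = np.triu_indices(size, 1)
    mask = rng.random(iu.size) < p
    return set(zip(iu[mask].tolist(), ju[mask].tolist()))


def _scale_free_edges(size: int, k: float, rng: np.random.Generator) -> set[Edge]:
    """Preferential attachment from a complete seed, topped up to n*k/2 edges.

    Growth adds ``round(k/2)`` (min 1) edges per new node; because growth alone
    undershoots the ``n*k/2`` edge budget at moderate module sizes, additional
    edges are drawn with both endpoints degree-proportional until the budget is
    met, which preserves the heavy-tailed degree distribution.
    """
    m = max(1, int(round(k / 2)))
    m = min(m, size - 1)
    target = _target_edges(size, k)
    edges: set[Edge] = {(i, j) for i in range(m + 1) for j in range(i + 1, m + 1)}
    # repeated-endpoint list: node i appears deg(i) times
    attach: list[int] = [x for e in edges for x in e]
    for new in range(m + 1, size):
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(attach[rng.integers(len(attach))])
        for t in chosen:
            edges.add(canonical_edge(t, new))
            attach.append(t)
            attach.append(new)
    tries = 0
    max_tries = 50 * max(1, target - len(edges)) + 100
    while len(edges) < target and tries < max_tries:
        tries += 1
        u = attach[rng.integers(len(attach))]
        v = attach[rng.integers(len(attach))]
        if u == v:
            continue
        e = canonical_edge(u, v)
        if e in edges:
            continue
        edges.add(e)
        attach.append(u)
        attach.append(v)
    return edges


def _scaled_exponential_degrees(
    raw: np.ndarray, cap: int, target: int, realized
) -> np.ndarray:
    """Scale sorted exponential draws so ``realized(degrees)`` reaches ``target``.

    ``raw`` is a descending array of Exponential(1) draws; degrees are
    ``clip(round(s * raw), 1, cap)`` and ``s`` is found by bisection on the
    monotone realized edge count.
    """

    def degrees(s: float) -> np.ndarray:
        return np.clip(np.round(s * raw).astype(int), 1, cap)

    hi = 1.0
    while realized(degrees(hi)) < target and hi < 8.0 * cap:
        hi *= 2.0
    lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(degrees(mid)) < target:
            lo = mid
        else:
            hi = mid
    return degrees(hi)


def _nested_edges(size: int, k: float, rng: np.random.Generator) -> set[Edge]:
    """Perfectly nested module with an exponential degree distribution.

    Node ids double as hub ranks. Each node ``j`` receives a target degree
    ``d_j`` from a scaled exponential law (descending in rank) and attaches to
    the ``d_j`` top-ranked hubs: edge (i, j), i<j, present iff ``i < d_j``.
    Neighbor sets are totally ordered by inclusion, and the scaling is chosen
    by bisection so the edge count lands on ``size*k/2``.
    """
    target = _target_edges(size, k)
    raw = np.sort(rng.exponential(1.0, size))[::-1]
    ranks = np.arange(size)

    def realized(d: np.ndarray) -> int:
        return int(np.minimum(d, ranks).sum())

    d = _scaled_exponential_degrees(raw, size - 1, target, realized)
    return {(i, j) for j in range(size) for i in range(min(int(d[j]), j))}


def _bipartite_nested_block(
    nA: int,
    nB: int,
    target: int,
    offA: int,
    offB: int,
    rng: np.random.Generator,
) -> set[Edge]:
    """Nested cross-guild block: side-B node of target degree d attaches to the
    d top-ranked side-A hubs, with exponential target degrees scaled to the
    block edge budget."""
    raw = np.sort(rng.exponential(1.0, nB))[::-1]
    d = _scaled_exponential_degrees(
        raw, nA, target, lambda deg: int(deg.sum())
    )
    edges = set()
    for b in range(nB):
        for a in range(int(d[b])):
            edges.add(canonical_edge(offA + a, offB + b))
    return edges


def _bipartite_random_block(
    nA: int, nB: int, target: int, offA: int, offB: int, rng: np.random.Generator
) -> set[Edge]:
    p = min(1.0, target / (nA * nB))
    aa, bb = np.meshgrid(np.arange(nA), np.arange(nB), indexing="ij")
    mask = rng.random(nA * nB) < p
    aa = aa.ravel()[mask]
    bb = bb.ravel()[mask]
    return {canonical_edge(offA + int(a), offB + int(b)) for a, b in zip(aa, bb)}


def _split_sizes(size: int, parts: int) -> list[int]:
    base = size // parts
    out = [base + (1 if i < size % parts else 0) for i in range(parts)]
    return out


def build_module(
    topology: str,
    size: int,
    k: float,
    rng: np.random.Generator | None = None,
) -> tuple[set[Edge], np.ndarray]:
    """Build one module on local node ids ``0..size-1``.

    Returns the edge set and per-node guild (level) labels. Bipartite and
    tripartite templates place the first guild on the lowest node ids; nested
    variants order nodes by decreasing rank within each guild.
    """
    if topology not in TOPOLOGIES:
        raise ConfigError(f"unknown topology {topology!r}")
    if size < MIN_TOPOLOGY_SIZE[topology]:
        raise ConfigError(
            f"topology {topology} needs at least {MIN_TOPOLOGY_SIZE[topology]} nodes, got {size}"
        )
    if k >= size:
        raise ConfigError("mean degree k must be smaller than the module size")
    rng = np.random.default_rng() if rng is None else rng
    guild = np.zeros(size, dtype=np.int8)

    if topology == "random":
        return _er_edges(size, k, rng), guild
    if topology == "scale_free":
        return _scale_free_edges(size, k, rng), guild
    if topology == "nested":
        return _nested_edges(size, k, rng), guild

    if topology.startswith("bipartite"):
        nA = (size + 1) // 2
        nB = size - nA
        guild[nA:] = 1
        target = _target_edges(size, k)
        target = min(target, nA * nB)
        if topology == "bipartite_nested":
            edges = _bipartite_nested_block(nA, nB, target, 0, nA, rng)
        else:
            edges = _bipartite_random_block(nA, nB, target, 0, nA, rng)
        return edges, guild

    # tripartite: levels 0-1-2, edges only between adjacent levels; each block
    # carries half the module's edge budget so the whole module hits n*k/2.
    n1, n2, n3 = _split_sizes(size, 3)
    guild[n1 : n1 + n2] = 1
    guild[n1 + n2 :] = 2
    per_block = int(round(size * k / 4))
    t12 = min(per_block, n1 * n2)
    t23 = min(per_block, n2 * n3)
    if topology == "tripartite_nested":
        edges = _bipartite_nested_block(n1, n2, t12, 0, n1, rng)
        edges |= _bipartite_nested_block(n2, n3, t23, n1, n1 + n2, rng)
    else:
        edges = _bipartite_random_block(n1, n2, t12, 0, n1, rng)
        edges |= _bipartite_random_block(n2, n3, t23, n1, n1 + n2, rng)
    return edges, guild


# ---------------------------------------------------------------------------
# rewiring
# ---------------------------------------------------------------------------


def _rewire(
    network: ModularNetwork,
    p: float,
    rng: np.random.Generator,
    local: bool,
) -> ModularNetwork:
    if p <= 0.0 or not network.edges:
        return network
    edges = sorted(network.edges)
    eset = set(edges)
    mod = network.module_of
    n = network.n_nodes
    for e in edges:
        if rng.random() >= p:
            continue
        u, v = e
        if rng.random() < 0.5:
            moved, kept = u, v
        else:
            moved, kept = v, u
        if local:
            pool = network.module_nodes(int(mod[moved]))
            new = int(pool[rng.integers(len(pool))])
        else:
            new = int(rng.integers(n))
        if new == kept:
            continue  # self-loop: reject, keep edge
        e2 = canonical_edge(kept, new)
        if e2 in eset:
            continue  # duplicate (includes new == moved): reject, keep edge
        eset.discard(e)
        eset.add(e2)
    return network.with_edges(eset)


def rewire_local(
    network: ModularNetwork, p_local: float, rng: np.random.Generator
) -> ModularNetwork:
    """Rewire each edge within its module with probability ``p_local``."""
    return _rewire(network, p_local, rng, local=True)


def rewire_global(
    network: ModularNetwork, p_rew: float, rng: np.random.Generator
) -> ModularNetwork:
    """Rewire each edge to an arbitrary node with probability ``p_rew``."""
    return _rewire(network, p_rew, rng, local=False)


# ---------------------------------------------------------------------------
# full generation
# ---------------------------------------------------------------------------


def generate_network(config: GeneratorConfig) -> ModularNetwork:
    """Generate a complete modular network from ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    draw = draw_module_sizes(config.N, config.M_av, config.min_module_size, rng)

    labels = [t for t in TOPOLOGIES if config.topology_mix.get(t, 0.0) > 0]
    probs = np.array([config.topology_mix[t] for t in labels], dtype=float)
    probs = probs / probs.sum()

    edges: set[Edge] = set()
    module_of = np.empty(config.N, dtype=np.int64)
    guild_of = np.empty(config.N, dtype=np.int8)
    module_type: dict[int, str] = {}
    offset = 0
    for mi, size in enumerate(draw.sizes):
        t = labels[int(rng.choice(len(labels), p=probs))]
        if size < MIN_TOPOLOGY_SIZE[t]:
            t = "random"  # drawn template infeasible at this size
        k_eff = min(config.k, size - 1)
        mod_edges, mod_guild = build_module(t, size, k_eff, rng)
        edges.update(canonical_edge(offset + u, offset + v) for u, v in mod_edges)
        module_of[offset : offset + size] = mi
        guild_of[offset : offset + size] = mod_guild
        module_type[mi] = t
        offset += size

    net = ModularNetwork(
        edges=edges, module_of=module_of, module_type=module_type, guild_of=guild_of
    )
    net = rewire_local(net, config.p_local, rng)
    net = rewire_global(net, config.p_rew, rng)
    return net


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------


def _draw_abundances(
    family: str, params: dict[str, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    if family == "exponential":
        rate = float(params.get("rate", 1.0))
        if rate <= 0:
            raise ConfigError("exponential rate must be positive")
        return rng.exponential(1.0 / rate, size)
    if family == "fisher_logseries":
        x = float(params.get("x", 0.99))
        if not (0.0 < x < 1.0):
            raise ConfigError("Fisher log-series x must lie in (0, 1)")
        return stats.logser.rvs(x, size=size, random_state=rng).astype(float)
    if family == "lognormal":
        mu = float(params.get("mu", 0.0))
        sigma = float(params.get("sigma", 1.0))
        if sigma <= 0:
            raise ConfigError("lognormal sigma must be positive")
        return rng.lognormal(mu, sigma, size)
    raise ConfigError(f"unknown abundance family {family!r}")


def assign_abundances(
    network: ModularNetwork,
    family: str = "exponential",
    params: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ModularNetwork:
    """Attach per-node abundances drawn independently within each module.

    Draws are i.i.d. within a module and shuffled over the module's nodes by a
    uniform random permutation, so abundance is structurally uncorrelated with
    degree or any other network property.
    """
    rng = np.random.default_rng() if rng is None else rng
    if params is None:
        params = dict(DEFAULT_ABUNDANCE_PARAMS[family]) if family in DEFAULT_ABUNDANCE_PARAMS else {}
    ab = np.empty(network.n_nodes, dtype=float)
    for m in range(network.n_modules):
        nodes = network.module_nodes(m)
        values = _draw_abundances(family, params, len(nodes), rng)
        ab[nodes] = values[rng.permutation(len(nodes))]
    return network.with_abundance(ab)
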