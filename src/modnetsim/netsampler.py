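"""Anchor/first-neighbor sampling of a complete network.

The sampling model emulates a field campaign: ``m`` attempts are made to pick
anchor species (with replacement, so repeats are lost), and each distinct
anchor's interactions are probed with a budget of first-neighbor attempts
(``nfn``). Only realized interactions enter the observed network — a true link
between two anchors is present only if one anchor was drawn as a neighbor of
the other.

Anchor schemes: uniform random, degree-proportional, abundance-proportional
(abundances drawn per module from a species-abundance distribution), or
module-weighted (uniform within modules). Neighbor draws are uniform or
weighted by per-node Exponential(1) weights fixed for the sampling run.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .config import SamplerConfig
from .errors import ConfigError, DegenerateGraphError, MissingAbundanceError
from .network import ModularNetwork, SampledNetwork, canonical_edge

__all__ = [
    "anchor_probabilities",
    "select_anchors",
    "neighbor_attempts",
    "sample_neighbors",
    "sample_network",
]


def anchor_probabilities(
    network: ModularNetwork, scheme: str, config: SamplerConfig
) -> np.ndarray:
    """Per-node anchor selection probabilities (non-negative, summing to 1)."""
    n = network.n_nodes
    if scheme == "random":
        return np.full(n, 1.0 / n)
    if scheme == "degree":
        deg = network.degrees.astype(float)
        total = deg.sum()
        if total == 0:
            raise DegenerateGraphError("degree scheme undefined on an edgeless network")
        return deg / total
    if scheme == "abundance":
        if network.abundance is None:
            raise MissingAbundanceError(
                "abundance scheme requires abundances assigned to the network"
            )
        ab = network.abundance.astype(float)
        return ab / ab.sum()
    if scheme == "module":
        if config.module_weights is None:
            raise ConfigError("module scheme requires module_weights")
        sizes = network.module_sizes()
        w = np.zeros(network.n_modules, dtype=float)
        for mi, wi in config.module_weights.items():
            if not (0 <= mi < network.n_modules):
                raise ConfigError(f"module weight for unknown module {mi}")
            w[mi] = wi
        total = w.sum()
        if total <= 0:
            raise ConfigError("module_weights must not all be zero")
        # uniform within each module: node prob = w_m / (size_m * W)
        per_node = np.where(sizes > 0, w / np.maximum(sizes, 1) / total, 0.0)
        return per_node[network.module_of]
    raise ConfigError(f"unknown anchor scheme {scheme!r}")


def select_anchors(
    network: ModularNetwork,
    config: SamplerConfig,
    rng: np.random.Generator,
    probabilities: np.ndarray | None = None,
) -> np.ndarray:
    """Perform ``m`` anchor draws with replacement; return the distinct set.

    A node drawn more than once counts only once, so the realized anchor count
    can fall below ``m``.
    """
    p = (
        anchor_probabilities(network, config.anchor_scheme, config)
        if probabilities is None
        else probabilities
    )
    draws = rng.choice(network.n_nodes, size=config.m, replace=True, p=p)
    return np.unique(draws)


def neighbor_attempts(degree: int, nfn_mode: str, nfn_value: float | None) -> int:
    """Number of neighbor-sampling attempts granted to an anchor of ``degree``."""
    if degree <= 0:
        return 0
    if nfn_mode == "all":
        return int(degree)
    if nfn_mode == "single":
        return 1
    if nfn_mode == "max_count":
        return int(nfn_value)
    if nfn_mode == "fraction":
        # round half up, with a floor of one attempt for non-isolated anchors
        return max(1, int(math.floor(nfn_value * degree + 0.5)))
    raise ConfigError(f"unknown nfn_mode {nfn_mode!r}")


def sample_neighbors(
    network: ModularNetwork,
    anchor: int,
    config: SamplerConfig,
    rng: np.random.Generator,
    node_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Draw neighbors of ``anchor`` with replacement; return the distinct set.

    ``node_weights`` (per-node exponential weights) are honored when the
    config requests exponential neighbor weighting; when the function is
    called standalone in that mode they are drawn on the spot.
    """
    nbrs = network.adjacency[anchor]
    d = nbrs.size
    attempts = neighbor_attempts(d, config.nfn_mode, config.nfn_value)
    if d == 0 or attempts == 0:
        return np.empty(0, dtype=np.int64)
    if config.nfn_mode == "all":
        return nbrs.copy()
    if config.neighbor_weighting == "exponential" and node_weights is None:
        node_weights = rng.exponential(1.0, network.n_nodes)
    if node_weights is None:
        idx = rng.integers(0, d, size=attempts)
    else:
        w = node_weights[nbrs]
        idx = rng.choice(d, size=attempts, replace=True, p=w / w.sum())
    return np.unique(nbrs[idx])


def sample_network(
    network: ModularNetwork,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> SampledNetwork:
    """Run one full sampling replicate and return the observed network.

    Anchors with no realized neighbors stay in the observed network as
    isolated nodes: they were observed species even if none of their
    interactions were.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng

    cfg = config
    if cfg.anchor_scheme == "module" and cfg.module_weights is None:
        # taxon-preference heterogeneity: one uniform weight per module per run
        w = rng.uniform(0.0, 1.0, network.n_modules)
        cfg = replace(cfg, module_weights={i: float(x) for i, x in enumerate(w)})

    probabilities = anchor_probabilities(network, cfg.anchor_scheme, cfg)
    anchors = select_anchors(network, cfg, rng, probabilities=probabilities)

    node_weights = None
    if cfg.neighbor_weighting == "exponential":
        node_weights = rng.exponential(1.0, network.n_nodes)

    nodes: set[int] = set(int(a) for a in anchors)
    edges: set[tuple[int, int]] = set()
    for a in anchors:
        a = int(a)
        chosen = sample_neighbors(network, a, cfg, rng, node_weights=node_weights)
        for v in chosen:
            v = int(v)
            nodes.add(v)
            edges.add(canonical_edge(a, v))

    return SampledNetwork(
        parent=network,
        anchors=frozenset(int(a) for a in anchors),
        nodes=frozenset(nodes),
        edges=edges,
    )
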