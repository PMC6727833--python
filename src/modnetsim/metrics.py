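"""Descriptors of observed networks.

The study's headline quantities: number of connected components, relative size
of the largest component (RSLC = largest component size / observed size),
observed network size, and true-vs-sampled degree pairs for comparing the
observed degree structure against the complete network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ModnetError
from .network import SampledNetwork

__all__ = [
    "MetricsRecord",
    "connected_components",
    "rslc",
    "observed_size",
    "summarize",
    "degree_pairs",
    "pooled_degree_histogram",
]


@dataclass
class MetricsRecord:
    """Per-replicate metric row (experiment keys optional)."""

    n_components: int
    rslc: float
    observed_size: int
    replicate_id: int | None = None
    topology: str | None = None
    anchor_scheme: str | None = None
    m: int | None = None
    nfn_mode: str | None = None
    nfn_value: float | None = None


def connected_components(
    nodes: Iterable[int], edges: Iterable[tuple[int, int]]
) -> list[set[int]]:
    """Partition ``nodes`` into maximal connected sets (isolates are singletons)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return [set(c) for c in nx.connected_components(g)]


def observed_size(sampled: SampledNetwork) -> int:
    return sampled.n_nodes


def rslc(sampled: SampledNetwork) -> float:
    """Relative size of the largest component of the observed network."""
    if sampled.n_nodes == 0:
        raise ModnetError("RSLC undefined on an empty observed network")
    comps = connected_components(sampled.nodes, sampled.edges)
    return max(len(c) for c in comps) / sampled.n_nodes


def summarize(sampled: SampledNetwork, **keys) -> MetricsRecord:
    """Compute the full metric record for one observed network."""
    if sampled.n_nodes == 0:
        raise ModnetError("metrics undefined on an empty observed network")
    comps = connected_components(sampled.nodes, sampled.edges)
    largest = max(len(c) for c in comps)
    return MetricsRecord(
        n_components=len(comps),
        rslc=largest / sampled.n_nodes,
        observed_size=sampled.n_nodes,
        **keys,
    )


def degree_pairs(sampled: SampledNetwork, anchors_only: bool = False) -> pd.DataFrame:
    """True vs sampled degree for each observed node.

    The sampled degree counts sampled edges only, so it never exceeds the true
    degree; with an exhaustive neighbor budget anchors sit on the diagonal.
    """
    obs_deg = sampled.degrees()
    true_deg = sampled.parent.degrees
    rows = []
    for node in sorted(sampled.nodes):
        is_anchor = node in sampled.anchors
        if anchors_only and not is_anchor:
            continue
        rows.append((node, int(true_deg[node]), obs_deg[node], is_anchor))
    return pd.DataFrame(
        rows, columns=["node", "true_degree", "sampled_degree", "is_anchor"]
    )


def pooled_degree_histogram(
    tables: Sequence[pd.DataFrame], bins: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool degree-pair tables from R realizations into a 2-D histogram.

    Returns ``(H, true_edges, sampled_edges)`` where ``H[i, j]`` counts nodes
    with true degree in bin i and sampled degree in bin j.
    """
    pooled = pd.concat(tables, ignore_index=True)
    return np.histogram2d(
        pooled["true_degree"].to_numpy(),
        pooled["sampled_degree"].to_numpy(),
        bins=bins,
    )
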