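"""In-memory containers for complete and sampled networks.

A :class:`ModularNetwork` is an undirected simple graph on nodes ``0..N-1``
with per-node module membership, per-module topology labels, per-node guild
(level) labels, and optional abundances. A :class:`SampledNetwork` is the
observed subgraph produced by anchor/first-neighbor sampling, holding a
reference to its parent network.

Networks are treated as immutable: operations that change the edge set return
a new object (sharing the metadata arrays), which lets adjacency structures be
cached safely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

Edge = tuple[int, int]


def canonical_edge(u: int, v: int) -> Edge:
    """Unordered pair as a sorted tuple."""
    return (u, v) if u < v else (v, u)


@dataclass(eq=False)
class ModularNetwork:
    """Complete (true) modular network.

    Parameters
    ----------
    edges:
        Set of unordered node pairs, each stored as ``(min, max)``.
    module_of:
        Array of length N mapping node -> module index.
    module_type:
        Map module index -> topology label.
    guild_of:
        Array of length N giving the level of each node within its module
        (0 for unipartite nodes; 0/1 for bipartite; 0/1/2 for tripartite).
    abundance:
        Optional strictly positive per-node abundances.
    """

    edges: set[Edge]
    module_of: np.ndarray
    module_type: dict[int, str]
    guild_of: np.ndarray
    abundance: np.ndarray | None = None

    _adj: list[np.ndarray] | None = field(default=None, repr=False, compare=False)
    _deg: np.ndarray | None = field(default=None, repr=False, compare=False)
    _module_nodes: dict[int, np.ndarray] | None = field(default=None, repr=False, compare=False)

    # -- basic shape ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.module_of)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_modules(self) -> int:
        return len(self.module_type)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.module_of, minlength=self.n_modules)

    def module_nodes(self, module: int) -> np.ndarray:
        if self._module_nodes is None:
            order = np.argsort(self.module_of, kind="stable")
            bounds = np.searchsorted(self.module_of[order], np.arange(self.n_modules + 1))
            self._module_nodes = {
                m: order[bounds[m] : bounds[m + 1]] for m in range(self.n_modules)
            }
        return self._module_nodes[module]

    # -- adjacency --------------------------------------------------------
    @property
    def degrees(self) -> np.ndarray:
        if self._deg is None:
            deg = np.zeros(self.n_nodes, dtype=np.int64)
            for u, v in self.edges:
                deg[u] += 1
                deg[v] += 1
            self._deg = deg
        return self._deg

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Neighbor arrays indexed by node (cached)."""
        if self._adj is None:
            nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for u, v in self.edges:
                nbrs[u].append(v)
                nbrs[v].append(u)
            self._adj = [np.array(sorted(b), dtype=np.int64) for b in nbrs]
        return self._adj

    def neighbors(self, node: int) -> np.ndarray:
        return self.adjacency[node]

    # -- derived views ----------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def inter_module_edge_count(self) -> int:
        mod = self.module_of
        return sum(1 for u, v in self.edges if mod[u] != mod[v])

    # -- copies -----------------------------------------------------------
    def with_edges(self, edges: set[Edge]) -> "ModularNetwork":
        return ModularNetwork(
            edges=set(edges),
            module_of=self.module_of,
            module_type=self.module_type,
            guild_of=self.guild_of,
            abundance=self.abundance,
        )

    def with_abundance(self, abundance: np.ndarray) -> "ModularNetwork":
        return ModularNetwork(
            edges=self.edges,
            module_of=self.module_of,
            module_type=self.module_type,
            guild_of=self.guild_of,
            abundance=np.asarray(abundance, dtype=float),
        )

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = self.n_nodes
        assert len(self.guild_of) == n
        for u, v in self.edges:
            assert 0 <= u < n and 0 <= v < n, "edge endpoint out of range"
            assert u < v, "edges must be canonical (min, max) pairs"
        assert int(self.module_sizes().sum()) == n, "module sizes must sum to N"
        assert set(np.unique(self.module_of)) <= set(self.module_type), (
            "every module index needs a topology label"
        )
        if self.abundance is not None:
            assert len(self.abundance) == n
            assert np.all(self.abundance > 0), "abundances must be strictly positive"

    def equals(self, other: "ModularNetwork") -> bool:
        return (
            self.edges == other.edges
            and np.array_equal(self.module_of, other.module_of)
            and dict(self.module_type) == dict(other.module_type)
            and np.array_equal(self.guild_of, other.guild_of)
            and (
                (self.abundance is None and other.abundance is None)
                or (
                    self.abundance is not None
                    and other.abundance is not None
                    and np.array_equal(self.abundance, other.abundance)
                )
            )
        )


@dataclass(eq=False)
class SampledNetwork:
    """Observed network produced by anchor/first-neighbor sampling.

    Only interactions realized during sampling are present: every edge has at
    least one anchor endpoint, and a true link between two anchors appears only
    if one anchor was drawn as a neighbor of the other.
    """

    parent: ModularNetwork
    anchors: frozenset[int]
    nodes: frozenset[int]
    edges: set[Edge]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_anchor(self, node: int) -> bool:
        return node in self.anchors

    def degrees(self) -> dict[int, int]:
        """Observed degree (sampled edges only) of every sampled node."""
        deg = {v: 0 for v in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        assert self.anchors <= self.nodes
        assert self.nodes <= set(range(self.parent.n_nodes))
        assert self.edges <= self.parent.edges, "sampled edges must exist in the parent"
        non_anchor_touched = set()
        for u, v in self.edges:
            assert u in self.nodes and v in self.nodes
            assert u in self.anchors or v in self.anchors, (
                "every sampled edge needs an anchor endpoint"
            )
            if u not in self.anchors:
                non_anchor_touched.add(u)
            if v not in self.anchors:
                non_anchor_touched.add(v)
        assert non_anchor_touched == set(self.nodes - self.anchors), (
            "every non-anchor must be adjacent to an anchor"
        )
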