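"""Readers, writers, and run manifests.

Canonical interchange is human-diffable tab-separated text:

* ``<prefix>.edges.tsv`` — two columns ``source	target``, lexicographically
  sorted canonical pairs, 0-based node ids.
* ``<prefix>.nodes.tsv`` — ``node	module	module_type	guild	abundance``
  (abundance blank when absent) plus ``is_anchor`` for observed networks.
* ``<prefix>.manifest.json`` — config snapshot, seeds, version, timestamps,
  output paths, for reproducible re-runs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import (
    DuplicateEdgeError,
    MissingMembershipError,
    SchemaError,
    SelfLoopError,
    UnknownNodeError,
)
from .network import ModularNetwork, SampledNetwork, canonical_edge

EDGE_SUFFIX = ".edges.tsv"
NODE_SUFFIX = ".nodes.tsv"
MANIFEST_SUFFIX = ".manifest.json"

__all__ = [
    "write_network",
    "read_network",
    "read_sampled",
    "write_table",
    "RunManifest",
]


def _edge_path(prefix) -> Path:
    return Path(str(prefix) + EDGE_SUFFIX)


def _node_path(prefix) -> Path:
    return Path(str(prefix) + NODE_SUFFIX)


def write_network(
    network: ModularNetwork | SampledNetwork, prefix
) -> dict[str, str]:
    """Write a complete or observed network as an edge list plus node table.

    Output ordering is stable (sorted) so identical networks produce identical
    files. Returns the written paths keyed by role.
    """
    edge_path = _edge_path(prefix)
    node_path = _node_path(prefix)
    edge_path.parent.mkdir(parents=True, exist_ok=True)

    sampled = isinstance(network, SampledNetwork)
    parent = network.parent if sampled else network
    node_ids = sorted(network.nodes) if sampled else range(parent.n_nodes)

    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")

    with open(node_path, "w") as fh:
        header = "node\tmodule\tmodule_type\tguild\tabundance"
        if sampled:
            header += "\tis_anchor"
        fh.write(header + "\n")
        for node in node_ids:
            mod = int(parent.module_of[node])
            ab = "" if parent.abundance is None else repr(float(parent.abundance[node]))
            row = f"{node}\t{mod}\t{parent.module_type[mod]}\t{int(parent.guild_of[node])}\t{ab}"
            if sampled:
                row += f"\t{int(node in network.anchors)}"
            fh.write(row + "\n")

    return {"edges": str(edge_path), "nodes": str(node_path)}


def _read_edges(prefix, node_set: set[int]) -> set[tuple[int, int]]:
    path = _edge_path(prefix)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas-specific parse failures
        raise SchemaError(f"cannot parse edge list {path}: {exc}") from exc
    if list(df.columns) != ["source", "target"]:
        raise SchemaError(f"edge list {path} must have columns source, target")
    edges: set[tuple[int, int]] = set()
    for raw_u, raw_v in df.itertuples(index=False):
        try:
            u, v = int(raw_u), int(raw_v)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-integer edge row ({raw_u!r}, {raw_v!r})") from exc
        if u == v:
            raise SelfLoopError(f"self-loop on node {u}")
        if u not in node_set or v not in node_set:
            raise UnknownNodeError(f"edge ({u}, {v}) references a node not in the node table")
        e = canonical_edge(u, v)
        if e in edges:
            raise DuplicateEdgeError(f"duplicate edge {e}")
        edges.add(e)
    return edges


def _read_nodes(prefix) -> pd.DataFrame:
    path = _node_path(prefix)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"node": int}, float_precision="round_trip")
    except ValueError as exc:
        raise SchemaError(f"cannot parse node table {path}: {exc}") from exc
    required = {"node", "module", "module_type", "guild"}
    if not required <= set(df.columns):
        raise SchemaError(f"node table {path} missing columns {sorted(required - set(df.columns))}")
    if df["node"].duplicated().any():
        raise SchemaError("duplicate node ids in node table")
    n = len(df)
    if sorted(df["node"]) != list(range(n)):
        raise SchemaError("node ids must be contiguous 0-based integers")
    if df["module"].isna().any():
        raise MissingMembershipError("node rows with missing module membership")
    return df.sort_values("node").reset_index(drop=True)


def read_network(prefix) -> ModularNetwork:
    """Read a complete network written by :func:`write_network` and validate it."""
    df = _read_nodes(prefix)
    n = len(df)
    module_of = df["module"].astype(int).to_numpy()
    guild_of = df["guild"].astype(int).to_numpy(dtype=np.int8)

    module_type: dict[int, str] = {}
    for mod, sub in df.groupby("module"):
        types = set(sub["module_type"])
        if len(types) != 1:
            raise SchemaError(f"module {mod} has inconsistent module_type labels {sorted(types)}")
        module_type[int(mod)] = str(types.pop())

    abundance = None
    if "abundance" in df.columns and df["abundance"].notna().any():
        if df["abundance"].isna().any():
            raise SchemaError("abundance present for some nodes but missing for others")
        abundance = df["abundance"].astype(float).to_numpy()
        if np.any(abundance <= 0):
            raise SchemaError("abundances must be strictly positive")

    edges = _read_edges(prefix, set(range(n)))
    net = ModularNetwork(
        edges=edges,
        module_of=module_of,
        module_type=module_type,
        guild_of=guild_of,
        abundance=abundance,
    )
    net.validate()
    return net


def read_sampled(prefix, parent: ModularNetwork) -> SampledNetwork:
    """Read an observed network (with is_anchor flags) against its parent."""
    df = pd.read_csv(_node_path(prefix), sep="\t")
    if "is_anchor" not in df.columns:
        raise SchemaError("observed-network node table needs an is_anchor column")
    nodes = frozenset(int(x) for x in df["node"])
    anchors = frozenset(int(x) for x, a in zip(df["node"], df["is_anchor"]) if int(a))
    edge_df = pd.read_csv(_edge_path(prefix), sep="\t")
    edges = {canonical_edge(int(u), int(v)) for u, v in edge_df.itertuples(index=False)}
    sampled = SampledNetwork(parent=parent, anchors=anchors, nodes=nodes, edges=edges)
    sampled.validate()
    return sampled


def write_table(df: pd.DataFrame, path) -> str:
    """Write a tidy metric/summary table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@dataclass
class RunManifest:
    """Record of one CLI/script run, sufficient to reproduce its outputs."""

    command: str
    config: dict
    seeds: dict
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, prefix) -> str:
        path = Path(str(prefix) + MANIFEST_SUFFIX)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return str(path)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
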