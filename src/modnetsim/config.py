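"""Configuration objects for network generation and sampling.

Two dataclasses carry every tunable of the simulation: :class:`GeneratorConfig`
for building the complete modular network and :class:`SamplerConfig` for the
anchor/first-neighbor sampling design. Both validate eagerly, serialize to flat
YAML mappings, and round-trip through :func:`GeneratorConfig.from_dict` /
:func:`SamplerConfig.from_dict`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ConfigError

#: Module topology templates, in canonical order.
TOPOLOGIES = (
    "random",
    "scale_free",
    "nested",
    "bipartite_nested",
    "bipartite_random",
    "tripartite_nested",
    "tripartite_random",
)

#: Smallest module size on which each template is defined
#: (bipartite needs two nodes per guild, tripartite two per level).
MIN_TOPOLOGY_SIZE = {
    "random": 2,
    "scale_free": 2,
    "nested": 2,
    "bipartite_nested": 4,
    "bipartite_random": 4,
    "tripartite_nested": 6,
    "tripartite_random": 6,
}

#: Default mix for "mixed" networks: uniform over the four headline templates.
DEFAULT_MIX = {
    "random": 0.25,
    "scale_free": 0.25,
    "nested": 0.25,
    "bipartite_nested": 0.25,
}

ANCHOR_SCHEMES = ("random", "degree", "abundance", "module")
NFN_MODES = ("all", "single", "max_count", "fraction")
NEIGHBOR_WEIGHTINGS = ("uniform", "exponential")
ABUNDANCE_FAMILIES = ("exponential", "fisher_logseries", "lognormal")

#: Conventional species-abundance parameter defaults.
DEFAULT_ABUNDANCE_PARAMS = {
    "exponential": {"rate": 1.0},
    "fisher_logseries": {"x": 0.99},
    "lognormal": {"mu": 0.0, "sigma": 1.0},
}


def single_type_mix(topology: str) -> dict[str, float]:
    """Topology mix that puts all probability on one template."""
    if topology not in TOPOLOGIES:
        raise ConfigError(f"unknown topology {topology!r}")
    return {topology: 1.0}


def _validate_mix(mix: Mapping[str, float]) -> dict[str, float]:
    if not mix:
        raise ConfigError("topology_mix must not be empty")
    out = {}
    for label, p in mix.items():
        if label not in TOPOLOGIES:
            raise ConfigError(f"unknown topology {label!r} in topology_mix")
        if p < 0:
            raise ConfigError("topology_mix probabilities must be non-negative")
        out[str(label)] = float(p)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"topology_mix probabilities sum to {total}, expected 1")
    return out


@dataclass
class GeneratorConfig:
    """All parameters of complete-network construction.

    Parameters
    ----------
    N:
        Total number of nodes (species).
    M_av:
        Mean module size; module sizes are drawn from an exponential law with
        this mean.
    k:
        Target mean node degree of the whole network.
    topology_mix:
        Map from topology label to selection probability (must sum to 1).
        ``None`` selects the default uniform mix over random / scale_free /
        nested / bipartite_nested.
    p_local, p_rew:
        Within-module and whole-network rewiring probabilities.
    min_module_size:
        Lower truncation of the module-size draw.
    seed:
        Seed for the generation random stream.
    """

    N: int = 500
    M_av: float = 25.0
    k: float = 10.0
    topology_mix: dict[str, float] | None = None
    p_local: float = 0.1
    p_rew: float = 0.1
    min_module_size: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ConfigError("N must be a positive integer")
        self.N = int(self.N)
        if self.M_av <= 0:
            raise ConfigError("M_av must be positive")
        if self.k <= 0:
            raise ConfigError("k must be positive")
        if int(self.min_module_size) != self.min_module_size or self.min_module_size < 2:
            raise ConfigError("min_module_size must be an integer >= 2")
        self.min_module_size = int(self.min_module_size)
        if not (self.min_module_size <= self.M_av <= self.N):
            raise ConfigError("require min_module_size <= M_av <= N")
        for name in ("p_local", "p_rew"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.topology_mix is None:
            self.topology_mix = dict(DEFAULT_MIX)
        else:
            self.topology_mix = _validate_mix(self.topology_mix)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["topology_mix"] = dict(self.topology_mix)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def parse_legacy_nfn(nfn: float) -> tuple[str, float | None]:
    """Map the legacy numeric nfn encoding onto an explicit mode.

    The historical convention: ``1`` adds all neighbors, ``1.1`` adds a single
    neighbor, an integer ``> 1`` is a maximum attempt count, and a value in
    ``(0, 1)`` is a fraction of the anchor's degree.
    """
    x = float(nfn)
    if math.isclose(x, 1.0, abs_tol=1e-9):
        return "all", None
    if math.isclose(x, 1.1, abs_tol=1e-9):
        return "single", None
    if 0.0 < x < 1.0:
        return "fraction", x
    if x > 1.0 and float(x).is_integer():
        return "max_count", int(x)
    raise ConfigError(f"cannot interpret legacy nfn value {nfn!r}")


@dataclass
class SamplerConfig:
    """All parameters of the anchor + first-neighbor sampling design.

    ``m`` counts anchor-selection *attempts* (draws with replacement), so the
    realized number of distinct anchors may fall below ``m``. ``nfn_mode`` /
    ``nfn_value`` set the per-anchor neighbor attempt budget; attempts that
    re-draw an already selected neighbor are lost.
    """

    m: int = 50
    nfn_mode: str = "max_count"
    nfn_value: float | int | None = 5
    anchor_scheme: str = "random"
    abundance_family: str = "exponential"
    abundance_params: dict[str, float] | None = None
    module_weights: dict[int, float] | None = None
    neighbor_weighting: str = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ConfigError("m must be a positive integer")
        self.m = int(self.m)
        if self.nfn_mode not in NFN_MODES:
            raise ConfigError(f"unknown nfn_mode {self.nfn_mode!r}")
        if self.nfn_mode == "max_count":
            v = self.nfn_value
            if v is None or int(v) != v or int(v) < 2:
                raise ConfigError("max_count nfn_value must be an integer >= 2")
            self.nfn_value = int(v)
        elif self.nfn_mode == "fraction":
            v = self.nfn_value
            if v is None or not (0.0 < float(v) < 1.0):
                raise ConfigError("fraction nfn_value must lie strictly in (0, 1)")
            self.nfn_value = float(v)
        else:
            self.nfn_value = None
        if self.anchor_scheme not in ANCHOR_SCHEMES:
            raise ConfigError(f"unknown anchor_scheme {self.anchor_scheme!r}")
        if self.neighbor_weighting not in NEIGHBOR_WEIGHTINGS:
            raise ConfigError(f"unknown neighbor_weighting {self.neighbor_weighting!r}")
        if self.abundance_family not in ABUNDANCE_FAMILIES:
            raise ConfigError(f"unknown abundance_family {self.abundance_family!r}")
        if self.abundance_params is None:
            self.abundance_params = dict(DEFAULT_ABUNDANCE_PARAMS[self.abundance_family])
        if self.module_weights is not None:
            w = {int(k): float(v) for k, v in self.module_weights.items()}
            if any(v < 0 for v in w.values()):
                raise ConfigError("module_weights must be non-negative")
            if sum(w.values()) <= 0:
                raise ConfigError("module_weights must not all be zero")
            self.module_weights = w

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.module_weights is not None:
            d["module_weights"] = dict(self.module_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SamplerConfig":
        d = dict(d)
        if "nfn" in d:  # legacy numeric encoding
            if "nfn_mode" in d or d.get("nfn_value") is not None:
                raise ConfigError("give either legacy 'nfn' or nfn_mode/nfn_value, not both")
            mode, value = parse_legacy_nfn(d.pop("nfn"))
            d["nfn_mode"] = mode
            d["nfn_value"] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown sampler config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SamplerConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
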