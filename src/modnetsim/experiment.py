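"""Replicated sampling experiments over topologies and sampling designs.

One complete network is generated per topology cell and re-sampled for many
replicates, isolating sampling variance from generation variance. Summaries
include per-cell means with standard errors, mean-RSLC-versus-m curves, and
all-pairs Tukey HSD comparisons of sampling designs with a compact letter
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import DEFAULT_MIX, GeneratorConfig, SamplerConfig, single_type_mix
from .errors import ConfigError, DegenerateDataError
from .metrics import summarize
from .netgen import assign_abundances, generate_network
from .netsampler import sample_network
from .network import ModularNetwork

__all__ = [
    "SCHEME_LABELS",
    "SweepSpec",
    "scheme_config",
    "network_for_topology",
    "run_replicates",
    "run_sweep",
    "rslc_vs_m_curve",
    "tukey_groups",
    "expected_size_limit",
    "plot_rslc_curves",
]

#: The five sampling designs compared in the study.
SCHEME_LABELS = (
    "random",
    "degree",
    "abundance_exponential",
    "abundance_lognormal",
    "module",
)

#: Topology cells: four uniform-module networks plus the mixed network.
TOPOLOGY_LABELS = ("random", "scale_free", "nested", "bipartite_nested", "mixed")


def scheme_config(label: str, base: SamplerConfig | None = None) -> SamplerConfig:
    """Concrete :class:`SamplerConfig` for a named sampling design."""
    base = SamplerConfig() if base is None else base
    if label == "random":
        return replace(base, anchor_scheme="random")
    if label == "degree":
        return replace(base, anchor_scheme="degree")
    if label == "abundance_exponential":
        return replace(
            base, anchor_scheme="abundance", abundance_family="exponential",
            abundance_params=None,
        )
    if label == "abundance_lognormal":
        return replace(
            base, anchor_scheme="abundance", abundance_family="lognormal",
            abundance_params=None,
        )
    if label == "module":
        return replace(base, anchor_scheme="module", module_weights=base.module_weights)
    raise ConfigError(f"unknown sampling design {label!r}")


def network_for_topology(
    topology: str, gen_template: GeneratorConfig, seed: int | None = None
) -> ModularNetwork:
    """Generate the complete network for one topology cell."""
    mix = dict(DEFAULT_MIX) if topology == "mixed" else single_type_mix(topology)
    cfg = replace(gen_template, topology_mix=mix, seed=gen_template.seed if seed is None else seed)
    return generate_network(cfg)


@dataclass
class SweepSpec:
    """Grid of a replicated sampling experiment."""

    topologies: Sequence[str] = TOPOLOGY_LABELS
    schemes: Sequence[str] = SCHEME_LABELS
    m_grid: Sequence[int] = tuple(range(10, 101, 10))
    nfn_grid: Sequence[int] = (5, 10)
    n_replicates: int = 1000
    base_seed: int = 0
    gen: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if not self.topologies or not self.schemes or not self.m_grid or not self.nfn_grid:
            raise ConfigError("sweep grids must be non-empty")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


def run_replicates(
    gen_config: GeneratorConfig,
    samp_config: SamplerConfig,
    n: int,
    base_seed: int,
    network: ModularNetwork | None = None,
    **keys,
) -> pd.DataFrame:
    """Sample one complete network ``n`` times; return a long metric table.

    The complete network is generated once (or passed in) and re-sampled for
    every replicate. Abundances, when the design needs them, are drawn once per
    network from a stream derived from ``base_seed`` and held fixed across
    replicates. Fully reproducible from ``(gen_config, samp_config, base_seed)``.
    """
    if network is None:
        network = generate_network(gen_config)
    ss = np.random.SeedSequence(base_seed)
    ab_ss, rep_ss = ss.spawn(2)
    if samp_config.anchor_scheme == "abundance" and network.abundance is None:
        network = assign_abundances(
            network,
            samp_config.abundance_family,
            samp_config.abundance_params,
            np.random.default_rng(ab_ss),
        )
    rows = []
    for i, child in enumerate(rep_ss.spawn(n)):
        rng = np.random.default_rng(child)
        sampled = sample_network(network, samp_config, rng)
        rec = summarize(
            sampled,
            replicate_id=i,
            anchor_scheme=samp_config.anchor_scheme,
            m=samp_config.m,
            nfn_mode=samp_config.nfn_mode,
            nfn_value=samp_config.nfn_value,
        )
        rows.append(rec)
    table = pd.DataFrame([r.__dict__ for r in rows])
    for key, value in keys.items():
        table[key] = value
    return table


def run_sweep(
    spec: SweepSpec, m: int | None = None, nfn: int | None = None
) -> pd.DataFrame:
    """Run every topology x scheme cell at one (m, nfn) point.

    ``m``/``nfn`` default to the first entries of ``spec``'s grids. Cell seeds
    are spawned deterministically from ``spec.base_seed``.
    """
    m = spec.m_grid[0] if m is None else m
    nfn = spec.nfn_grid[0] if nfn is None else nfn
    ss = np.random.SeedSequence(spec.base_seed)
    tables = []
    for topology in spec.topologies:
        net_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        network = network_for_topology(topology, spec.gen, seed=net_seed)
        for scheme in spec.schemes:
            cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            cfg = scheme_config(
                scheme, SamplerConfig(m=m, nfn_mode="max_count", nfn_value=nfn)
            )
            t = run_replicates(
                spec.gen, cfg, spec.n_replicates, cell_seed,
                network=network, topology=topology, scheme=scheme,
            )
            tables.append(t)
    return pd.concat(tables, ignore_index=True)


def rslc_vs_m_curve(
    spec: SweepSpec, topology: str | None = None, nfn: int | None = None
) -> pd.DataFrame:
    """Mean RSLC by (scheme, m) at fixed nfn for one topology cell."""
    topology = spec.topologies[0] if topology is None else topology
    nfn = spec.nfn_grid[0] if nfn is None else nfn
    ss = np.random.SeedSequence(spec.base_seed)
    net_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    network = network_for_topology(topology, spec.gen, seed=net_seed)
    rows = []
    for scheme in spec.schemes:
        for m in spec.m_grid:
            cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            cfg = scheme_config(
                scheme, SamplerConfig(m=m, nfn_mode="max_count", nfn_value=nfn)
            )
            t = run_replicates(spec.gen, cfg, spec.n_replicates, cell_seed, network=network)
            rows.append(
                {
                    "topology": topology,
                    "scheme": scheme,
                    "m": m,
                    "nfn": nfn,
                    "mean_rslc": t["rslc"].mean(),
                    "se_rslc": t["rslc"].std(ddof=1) / np.sqrt(len(t)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey HSD with compact letter display
# ---------------------------------------------------------------------------


def _compact_letters(
    groups: Sequence[str], means: dict[str, float], rejected: set[frozenset]
) -> dict[str, str]:
    """Compact letter display: groups share a letter iff some maximal clique of
    the non-significance graph contains both."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    for a in groups:
        for b in groups:
            if a < b and frozenset((a, b)) not in rejected:
                g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: (-max(means[x] for x in c), sorted(c)))
    letters = {grp: "" for grp in groups}
    for letter_idx, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_idx)
        for grp in clique:
            letters[grp] += letter
    return {grp: "".join(sorted(s)) for grp, s in letters.items()}


def tukey_groups(
    table: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    group_col: str = "scheme",
) -> pd.DataFrame:
    """All-pairs Tukey HSD over groups of a replicate table.

    Returns one row per group with mean, standard error, and a compact letter
    display: groups sharing a letter are not significantly different at
    ``alpha`` under the studentized-range procedure.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise DegenerateDataError("Tukey HSD needs at least two groups")
    sizes = table.groupby(group_col)[metric].size()
    if (sizes < 2).any():
        raise DegenerateDataError("Tukey HSD needs at least two replicates per group")
    values = table[metric].to_numpy(dtype=float)
    labels = table[group_col].to_numpy()
    means = {g: float(table.loc[labels == g, metric].mean()) for g in groups}
    ses = {
        g: float(
            table.loc[labels == g, metric].std(ddof=1) / np.sqrt((labels == g).sum())
        )
        for g in groups
    }

    pooled_within_var = float(
        table.groupby(group_col)[metric].var(ddof=1).fillna(0.0).mean()
    )
    rejected: set[frozenset] = set()
    if pooled_within_var == 0.0:
        # degenerate: no within-group spread, so any mean difference is exact
        if len({round(v, 15) for v in means.values()}) == 1:
            pass  # identical constants: trivially no differences
        elif np.var(values) == 0.0:
            pass
        else:
            raise DegenerateDataError(
                "zero within-group variance with differing means: "
                "studentized-range test undefined"
            )
    else:
        from itertools import combinations

        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        uniq = list(res.groupsunique)
        for (i, j), reject in zip(combinations(range(len(uniq)), 2), res.reject):
            if reject:
                rejected.add(frozenset((uniq[i], uniq[j])))

    letters = _compact_letters(groups, means, rejected)
    return pd.DataFrame(
        {
            group_col: groups,
            "mean": [means[g] for g in groups],
            "se": [ses[g] for g in groups],
            "letters": [letters[g] for g in groups],
        }
    )


def expected_size_limit(m: int, nfn: float, k: float) -> float:
    """Asymptotic observed-size reference: m*nfn when nfn << k, m*k when k << nfn.

    A diagnostic overlay for size curves, not a fitted quantity.
    """
    if m <= 0 or nfn <= 0 or k <= 0:
        raise ConfigError("expected_size_limit needs positive arguments")
    return float(m * min(nfn, k))


def plot_rslc_curves(curve: pd.DataFrame, path) -> None:
    """Convenience line plot of mean RSLC vs m, one line per scheme."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for scheme, sub in curve.groupby("scheme"):
        sub = sub.sort_values("m")
        ax.errorbar(sub["m"], sub["mean_rslc"], yerr=sub["se_rslc"], label=scheme)
    ax.set_xlabel("anchor attempts m")
    ax.set_ylabel("mean RSLC")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
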