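"""Figure rendering: lattice view, bipartite view, projections, ensembles.

All figures are deterministic functions of their inputs: layouts either
have closed forms (grid, two-column bipartite) or take an explicit seed,
and SVG output is written with a fixed hash salt and no timestamp so
repeated invocations are byte-identical.

Lattice edge styling generalises the classic four classes to any F:
endpoints sharing all F features draw no line, sharing more than half
draw a dotted line, sharing at most half (but some) a dashed line, and
sharing nothing a thick solid line — the frozen boundaries.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .bipartite import agent_nodes, attitude_nodes
from .clusters import ClusterSummary
from .config import ModelConfig
from .ensemble import EnsembleResult, cluster_density, mean_clusters_table
from .lattice import LatticeTopology
from .state import CultureState

# white / blue / red on dark, strongest to weakest
BIN_COLORS = ["#d62728", "#1f77b4", "#ffffff"]
DARK_BG = "#1c1c1c"


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in (".png", ".svg"):
        raise ValueError(f"output format must be png or svg, got {path.suffix!r}")
    kwargs = {}
    if path.suffix.lower() == ".svg":
        with matplotlib.rc_context({"svg.hashsalt": "axelrod-groups"}):
            fig.savefig(path, metadata={"Date": None}, **kwargs)
    else:
        fig.savefig(path, **kwargs)
    plt.close(fig)
    return path


def lattice_edge_class(shared: int, F: int) -> str:
    """Edge style class from the shared-feature count of its endpoints."""
    if shared == F:
        return "none"
    if shared > F / 2:
        return "dotted"
    if shared > 0:
        return "dashed"
    return "solid"


_EDGE_STYLE = {
    "dotted": {"linestyle": ":", "linewidth": 0.9, "color": "0.45"},
    "dashed": {"linestyle": "--", "linewidth": 1.1, "color": "0.25"},
    "solid": {"linestyle": "-", "linewidth": 2.6, "color": "black"},
}


def _culture_colors(state: CultureState) -> np.ndarray:
    """One stable colour per distinct culture vector."""
    _, inverse = np.unique(state.traits, axis=0, return_inverse=True)
    cmap = plt.get_cmap("tab20")
    return cmap(inverse % 20)


def plot_lattice(
    state: CultureState,
    topology: LatticeTopology,
    path: str | Path,
    node_size: float = 60.0,
) -> Path:
    """Grid view: nodes coloured by culture, edges styled by similarity."""
    L = topology.L
    xy = np.array([(i % L, L - 1 - i // L) for i in range(topology.N)], float)
    fig, ax = plt.subplots(figsize=(max(4, L * 0.5),) * 2)
    for u, v in zip(topology.edge_u, topology.edge_v):
        shared = int(np.count_nonzero(state.traits[u] == state.traits[v]))
        cls = lattice_edge_class(shared, state.F)
        if cls == "none":
            continue
        ax.plot(*zip(xy[u], xy[v]), zorder=1, **_EDGE_STYLE[cls])
    ax.scatter(xy[:, 0], xy[:, 1], s=node_size, c=_culture_colors(state),
               zorder=2, edgecolors="black", linewidths=0.3)
    ax.set_aspect("equal")
    ax.axis("off")
    return _save(fig, path)


def plot_bipartite(
    state: CultureState,
    bipartite: nx.Graph,
    path: str | Path,
) -> Path:
    """Two-column layout: agents left, attitude nodes right by feature."""
    agents = sorted(agent_nodes(bipartite))
    atts = sorted(
        attitude_nodes(bipartite),
        key=lambda n: (bipartite.nodes[n]["feature"], bipartite.nodes[n]["trait"]),
    )
    pos = {n: (0.0, -i / max(1, len(agents) - 1)) for i, n in enumerate(agents)}
    pos.update(
        {n: (1.0, -i / max(1, len(atts) - 1)) for i, n in enumerate(atts)}
    )
    cmap = plt.get_cmap("tab10")
    att_colors = [cmap(bipartite.nodes[n]["feature"] % 10) for n in atts]
    fig, ax = plt.subplots(figsize=(6, max(4, len(agents) * 0.06)))
    nx.draw_networkx_edges(bipartite, pos, ax=ax, alpha=0.25, width=0.5)
    nx.draw_networkx_nodes(bipartite, pos, nodelist=agents, node_size=18,
                           node_color="0.4", ax=ax)
    nx.draw_networkx_nodes(bipartite, pos, nodelist=atts, node_size=120,
                           node_color=att_colors, ax=ax)
    nx.draw_networkx_labels(
        bipartite, pos, labels={n: n for n in atts}, font_size=6, ax=ax
    )
    ax.axis("off")
    return _save(fig, path)


def agent_edge_class(weight: int, F: int) -> int:
    """Agreement class of an agent-projection edge: 2 = all F shared,
    1 = F-1 shared, 0 = fewer."""
    if weight >= F:
        return 2
    if weight == F - 1:
        return 1
    return 0


def plot_projection(
    projection: nx.Graph,
    path: str | Path,
    F: int | None = None,
    giant_component_only: bool = False,
    layout_seed: int = 0,
) -> Path:
    """Projection view on a dark background, edges coloured by class.

    Attitude projections colour by the weight-tercile ``bin`` attribute
    (call :func:`bin_edge_weights` first); agent projections colour by
    agreement class (all F / F-1 / fewer), which requires ``F``.
    """
    g = projection
    if giant_component_only and g.number_of_nodes():
        comps = list(nx.connected_components(g))
        if comps:
            g = g.subgraph(max(comps, key=len)).copy()
    pos = nx.spring_layout(g, seed=layout_seed, weight="weight")
    if g.graph.get("projection") == "agent":
        if F is None:
            raise ValueError("agent projections need F for agreement classes")
        classes = [agent_edge_class(w, F) for _, _, w in g.edges(data="weight")]
    else:
        classes = [d.get("bin", 0) for _, _, d in g.edges(data=True)]
    colors = [BIN_COLORS[min(c, len(BIN_COLORS) - 1)] for c in classes]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_facecolor(DARK_BG)
    fig.patch.set_facecolor(DARK_BG)
    nx.draw_networkx_edges(g, pos, ax=ax, edge_color=colors, width=1.0, alpha=0.8)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=40, node_color="#bbbbbb",
                           edgecolors="black", linewidths=0.3)
    ax.axis("off")
    return _save(fig, path)


def plot_mean_clusters(result: EnsembleResult, path: str | Path) -> Path:
    """Mean cluster count versus F, one line per agreement threshold."""
    table = mean_clusters_table(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    for a, sub in table.groupby("a", dropna=False, sort=True):
        sub = sub.sort_values("F")
        label = "standard" if a is None or (isinstance(a, float) and np.isnan(a)) \
            else f"a = {int(a)}"
        ax.errorbar(sub["F"], sub["mean_clusters"], yerr=sub["se_clusters"],
                    marker="o", capsize=2, label=label)
    ax.set_xlabel("number of features F")
    ax.set_ylabel("mean number of clusters")
    ax.legend()
    return _save(fig, path)


def plot_cluster_density(
    result: EnsembleResult, path: str | Path, **cell_filter
) -> Path:
    """Discrete density of the cluster count, one curve per threshold."""
    runs = result.runs
    a_values = sorted(
        {a for a in runs["a"].unique() if a is not None and not (
            isinstance(a, float) and np.isnan(a))}
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    if a_values:
        for a in a_values:
            dens = cluster_density(result, a=int(a), **cell_filter)
            ax.plot(dens.index, dens.values, marker=".", label=f"a = {int(a)}")
        ax.legend()
    else:
        dens = cluster_density(result, **cell_filter)
        ax.plot(dens.index, dens.values, marker=".")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("probability density")
    return _save(fig, path)
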