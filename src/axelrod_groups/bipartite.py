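"""Bipartite representation of a culture state and its 1-mode projections.

The two-mode graph has agent nodes (integers ``0..N-1``) on one side and
attitude nodes — (feature, trait) pairs — on the other; an edge records
that the agent holds that trait on that feature.  Every agent therefore
has degree exactly F and the graph has N*F edges.  Projecting onto the
attitude side gives a co-occurrence network (edge weight = number of
agents holding both attitudes; never an edge between two traits of the
same feature), and projecting onto the agent side links agents by the
number of features they share (weight F means identical cultures).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .state import CultureState

AGENT = 0
ATTITUDE = 1


def attitude_node(feature: int, trait: int) -> str:
    """Canonical id of the attitude node for (feature, trait)."""
    return f"f{feature}:t{trait}"


def build_bipartite(state: CultureState, all_nodes: bool = False) -> nx.Graph:
    """Two-mode graph of agents versus the (feature, trait) attitudes.

    By default only attitudes held by at least one agent are present;
    ``all_nodes=True`` adds every one of the F*q combinations (requires a
    known trait range ``state.q``), which keeps layouts comparable across
    states.
    """
    g = nx.Graph()
    g.add_nodes_from(range(state.N), bipartite=AGENT, kind="agent")
    if all_nodes:
        if state.q is None:
            raise ValueError("all_nodes=True requires a known trait range q")
        for k in range(state.F):
            for t in range(state.q):
                g.add_node(attitude_node(k, t), bipartite=ATTITUDE,
                           kind="attitude", feature=k, trait=t)
    for i in range(state.N):
        for k in range(state.F):
            t = int(state.traits[i, k])
            node = attitude_node(k, t)
            if node not in g:
                g.add_node(node, bipartite=ATTITUDE, kind="attitude",
                           feature=k, trait=t)
            g.add_edge(i, node)
    return g


def agent_nodes(bipartite: nx.Graph) -> list[int]:
    return [n for n, d in bipartite.nodes(data=True) if d["bipartite"] == AGENT]


def attitude_nodes(bipartite: nx.Graph) -> list[str]:
    return [n for n, d in bipartite.nodes(data=True) if d["bipartite"] == ATTITUDE]


def attitude_projection(bipartite: nx.Graph) -> nx.Graph:
    """Weighted co-occurrence graph over attitude nodes.

    weight(u, v) = number of agents holding both u and v.  Attitudes of
    the same feature are never linked (an agent holds one trait per
    feature).
    """
    nodes = attitude_nodes(bipartite)
    proj = nx.bipartite.weighted_projected_graph(bipartite, nodes)
    proj.graph["projection"] = "attitude"
    return proj


def agent_projection(bipartite: nx.Graph, min_weight: int = 1) -> nx.Graph:
    """Weighted agent graph: weight(i, j) = number of shared features.

    Edges below ``min_weight`` shared features are dropped; agents
    sharing no attitude with anyone remain as isolated nodes.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    nodes = agent_nodes(bipartite)
    proj = nx.bipartite.weighted_projected_graph(bipartite, nodes)
    if min_weight > 1:
        drop = [
            (u, v) for u, v, w in proj.edges(data="weight") if w < min_weight
        ]
        proj.remove_edges_from(drop)
    proj.graph["projection"] = "agent"
    proj.graph["min_weight"] = min_weight
    return proj


def bin_edge_weights(projection: nx.Graph, n_bins: int = 3) -> list[float]:
    """Label each edge with a weight bin (0 = weakest ... n_bins-1).

    Edges are split into ``n_bins`` classes by rank terciles (generally,
    quantiles) of the observed weight distribution; an edge whose weight
    ties a bin boundary goes to the lower bin, so the labelling is
    deterministic and order-independent.  Writes a ``bin`` attribute on
    every edge and returns the upper boundary weight of each bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    weights = sorted(w for _, _, w in projection.edges(data="weight"))
    if not weights:
        projection.graph["bin_boundaries"] = []
        return []
    E = len(weights)
    boundaries = [
        float(weights[min(E - 1, (E * (b + 1)) // n_bins - 1)] if (E * (b + 1)) // n_bins > 0 else weights[0])
        for b in range(n_bins)
    ]
    # enforce monotone boundaries (heavy ties can make ranks collapse)
    for b in range(1, n_bins):
        boundaries[b] = max(boundaries[b], boundaries[b - 1])
    for u, v, w in projection.edges(data="weight"):
        b = 0
        while b < n_bins - 1 and w > boundaries[b]:
            b += 1
        projection.edges[u, v]["bin"] = b
    projection.graph["bin_boundaries"] = boundaries
    return boundaries


# --------------------------------------------------------------- file I/O


def export_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a graph as GraphML or a whitespace-delimited weighted edge list."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif format == "edgelist":
        with path.open("w") as fh:
            for u, v, data in graph.edges(data=True):
                w = data.get("weight", 1)
                fh.write(f"{u} {v} {w}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph`.

    GraphML stores node ids as strings; agent ids are restored to
    integers so a round trip reproduces the original node set.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        mapping = {}
        for n, d in g.nodes(data=True):
            if d.get("kind") == "agent" or (isinstance(n, str) and n.isdigit()):
                mapping[n] = int(n)
        return nx.relabel_nodes(g, mapping)
    if format == "edgelist":
        g = nx.Graph()
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                u, v, w = parts[0], parts[1], float(parts[2])
                u = int(u) if u.isdigit() else u
                v = int(v) if v.isdigit() else v
                g.add_edge(u, v, weight=int(w) if w.is_integer() else w)
        return g
    raise ValueError(f"unknown export format {format!r}")
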