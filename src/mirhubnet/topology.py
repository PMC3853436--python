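"""Per-node centralities and whole-network topology summaries.

Edges are treated as unweighted for all path computations (MI weights rank
interactions but the tabulated topology is hop-count based). Conventions:

* betweenness — Brandes shortest-path betweenness, fractional credit over
  equally short paths, *unnormalized* (pair counts);
* closeness — (n_c - 1) / sum of distances within the node's connected
  component of size n_c (0 for an isolated node);
* clustering — local transitivity, 0 for degree < 2;
* centralization — Freeman degree centralization,
  sum(max_deg - deg_v) / ((n - 1)(n - 2)), 1 for a star;
* heterogeneity — sd(degree) / mean(degree) (population sd);
* characteristic path length — mean distance over connected ordered pairs;
  diameter/radius — max/min eccentricity in the largest component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import networkx as nx

from .exceptions import InputError, ParameterError
from .mi import MiNetwork

logger = logging.getLogger(__name__)

__all__ = ["TopologySummary", "node_centralities", "network_summary", "removal_curve"]


@dataclass
class TopologySummary:
    """The tabulated whole-network statistics."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_betweenness: float
    avg_clustering: float
    avg_closeness: float
    density: float
    heterogeneity: float
    centralization: float
    char_path_length: float
    diameter: int
    radius: int

    def to_dict(self) -> dict:
        return asdict(self)


def _graph(network) -> nx.Graph:
    return network.graph if isinstance(network, MiNetwork) else network


def node_centralities(network) -> pd.DataFrame:
    """Degree, betweenness, closeness and clustering per node."""
    g = _graph(network)
    if g.number_of_nodes() == 0:
        raise InputError("network has no nodes")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=False)
    clu = nx.clustering(g)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "clustering": [clu[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _char_path_length(g: nx.Graph) -> float:
    """Mean shortest-path distance over connected ordered pairs (nan if none)."""
    total, pairs = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    return total / pairs if pairs else float("nan")


def network_summary(network) -> TopologySummary:
    g = _graph(network)
    n = g.number_of_nodes()
    if n == 0:
        raise InputError("network has no nodes")
    cent = node_centralities(network)
    degrees = cent["degree"].to_numpy(dtype=float)
    n_edges = g.number_of_edges()
    density = 2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    if n < 3:
        logger.warning("centralization undefined for n < 3; reported as 0")
        centralization = 0.0
    else:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    if n_edges:
        comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        sub = g.subgraph(comp)
        ecc = nx.eccentricity(sub)
        diameter, radius = max(ecc.values()), min(ecc.values())
    else:
        diameter = radius = 0
    return TopologySummary(
        n_nodes=n,
        n_edges=n_edges,
        avg_degree=float(mean_deg),
        avg_betweenness=float(cent["betweenness"].mean()),
        avg_clustering=float(cent["clustering"].mean()),
        avg_closeness=float(cent["closeness"].mean()),
        density=float(density),
        heterogeneity=heterogeneity,
        centralization=centralization,
        char_path_length=float(_char_path_length(g)),
        diameter=int(diameter),
        radius=int(radius),
    )


def removal_curve(network, top_n: int = 10) -> pd.DataFrame:
    """Remove the ``top_n`` highest-degree nodes one at a time.

    Nodes are ranked on the intact network by degree (ties broken by
    lexicographic ID); after each removal the average degree and
    characteristic path length of the remaining graph are recomputed.
    Returns ``top_n + 1`` rows including the intact network (step 0).
    """
    g = _graph(network).copy()
    if top_n >= g.number_of_nodes():
        raise ParameterError("top_n must be smaller than the number of nodes")
    order = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    victims = [v for v, _ in order[:top_n]]
    rows = []

    def snapshot(step):
        n = g.number_of_nodes()
        avg_deg = 2.0 * g.number_of_edges() / n if n else 0.0
        rows.append((step, avg_deg, _char_path_length(g)))

    snapshot(0)
    for step, v in enumerate(victims, start=1):
        g.remove_node(v)
        snapshot(step)
    return pd.DataFrame(rows, columns=["removed_count", "avg_degree", "char_path_length"])
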