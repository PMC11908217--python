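"""Hydrophobic residue interaction graphs and closeness centrality.

Nodes are residues; an edge joins two residues whose *mean* hydrophobic
contact frequency across the temperature ladder exceeds a threshold
(default 0.75, i.e. only temperature-stable contacts), weighted by that
mean. Closeness centrality of residue i is

    C_i = (n - 1) / sum_j d(i, j)

with d the unweighted shortest-path hop count. On graphs with several
components the component-scaled generalization
C_i = (r_i - 1)/sum_d * (r_i - 1)/(n - 1) is used (r_i = size of i's
component), which reduces exactly to the formula above on connected graphs;
isolated nodes score 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import ContactFrequencyMatrix
from .structure_io import ResidueLabel

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


def build_hydrophobic_graph(matrix: ContactFrequencyMatrix,
                            threshold: float = 0.75) -> nx.Graph:
    """Graph of residue pairs whose mean hydrophobic frequency > threshold."""
    hyd = matrix.restrict_to_type("hydrophobic")
    graph = nx.Graph()
    if len(hyd.keys) == 0:
        logger.info("no hydrophobic contacts in matrix; empty graph")
        return graph
    means = hyd.values.mean(axis=1)
    for key, mean in zip(hyd.keys, means):
        if mean > threshold:
            graph.add_edge(key.res_a, key.res_b, weight=float(mean))
    return graph


@dataclass
class CentralityProfile:
    """Per-node closeness centrality in [0, 1]."""

    centrality: dict[ResidueLabel, float]
    n_nodes: int

    def as_series(self) -> pd.Series:
        keys = sorted(self.centrality, key=lambda r: r.sort_key)
        return pd.Series([self.centrality[k] for k in keys],
                         index=[str(k) for k in keys], name="closeness")


def closeness_centrality(graph: nx.Graph, *,
                         weighted: bool = False) -> CentralityProfile:
    """Closeness centrality of every node (see module docstring).

    ``weighted=True`` uses edge weights as inverse affinities
    (distance = 1/weight) instead of hop counts; off by default since the
    centrality formula is stated over unweighted path lengths.
    """
    if graph.number_of_nodes() == 0:
        return CentralityProfile(centrality={}, n_nodes=0)
    if weighted:
        dist_graph = graph.copy()
        for u, v, d in dist_graph.edges(data=True):
            d["distance"] = 1.0 / d["weight"]
        cc = nx.closeness_centrality(dist_graph, distance="distance",
                                     wf_improved=True)
    else:
        cc = nx.closeness_centrality(graph, wf_improved=True)
    return CentralityProfile(centrality={n: float(c) for n, c in cc.items()},
                             n_nodes=graph.number_of_nodes())


def top_cc_subnetwork(graph: nx.Graph, profile: CentralityProfile,
                      fraction: float = 0.20) -> nx.Graph:
    """Induced subgraph on the top ``ceil(fraction * n)`` nodes by closeness.

    Ties break by residue order (chain, number, insertion code).
    """
    if not (0 < fraction <= 1):
        raise NetworkError(f"fraction must be in (0, 1], got {fraction}")
    nodes = list(graph.nodes)
    if not nodes:
        return nx.Graph()
    keep = math.ceil(fraction * len(nodes))
    ranked = sorted(nodes, key=lambda n: (-profile.centrality.get(n, 0.0),
                                          n.sort_key))
    return graph.subgraph(ranked[:keep]).copy()


def edges_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [(str(u), str(v), float(d.get("weight", 1.0)))
            for u, v, d in sorted(graph.edges(data=True),
                                  key=lambda e: (e[0].sort_key, e[1].sort_key))]
    return pd.DataFrame(rows, columns=["resA", "resB", "weight"])


def write_graphml(graph: nx.Graph, path) -> None:
    # GraphML needs string node ids
    relabeled = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    nx.write_graphml(relabeled, str(path))
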