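"""Topological summary statistics for the enzyme and gene networks.

The same five quantities are reported for every construction stage — node
count, edge count, clustering coefficient, average shortest-path length and
Freeman degree centralization — so the effect of each transformation
(filtering, homology fan-out, expression weighting) shows up as a change in
network shape.

Conventions, chosen where the field admits more than one:

* clustering default is global transitivity, 3 x triangles / connected
  triples; the average-local variant (mean local clustering over nodes of
  degree >= 2) is also available and both appear in reports;
* average path length is taken over *connected* unordered pairs only, with
  the number of excluded (disconnected) pairs surfaced alongside, rather
  than penalizing or dropping components silently;
* quantities undefined on a given graph (path length of an edgeless graph,
  centralization below three nodes) are NaN, not an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import pandas as pd


class PathLengthResult(NamedTuple):
    value: float            # mean distance over connected pairs; NaN if none
    excluded_pairs: int     # unordered pairs in different components


@dataclass
class TopologySummary:
    """One row of the per-network report."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    clustering_coefficient_local: float
    average_path_length: float
    excluded_pairs: int
    centralization: float


def clustering_coefficient(net: nx.Graph, mode: str = "global") -> float:
    """Clustering coefficient of an undirected simple graph.

    mode="global": transitivity (3 x triangles / connected triples);
    mode="average-local": mean local clustering over nodes of degree >= 2.
    A graph with no connected triple scores 0.
    """
    if mode == "global":
        return float(nx.transitivity(net))
    if mode == "average-local":
        eligible = [n for n in net if net.degree(n) >= 2]
        if not eligible:
            return 0.0
        local = nx.clustering(net, eligible)
        return float(sum(local.values()) / len(eligible))
    raise ValueError(f"mode must be 'global' or 'average-local', got {mode!r}")


def average_path_length(net: nx.Graph) -> PathLengthResult:
    """Mean shortest-path distance over connected unordered node pairs.

    Pairs in different components are excluded and counted. A graph with no
    connected pair (single node, edgeless) yields NaN.
    """
    n = net.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    dist_sum = 0
    connected_pairs = 0
    for component in nx.connected_components(net):
        sub = net.subgraph(component)
        for source, lengths in nx.all_pairs_shortest_path_length(sub):
            for target, d in lengths.items():
                if target != source:
                    dist_sum += d
                    connected_pairs += 1
    connected_pairs //= 2  # each pair counted in both directions
    dist_sum //= 2
    excluded = total_pairs - connected_pairs
    if connected_pairs == 0:
        return PathLengthResult(math.nan, excluded)
    return PathLengthResult(dist_sum / connected_pairs, excluded)


def degree_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization: sum_i (d_max - d_i) / ((n-1)(n-2)).

    1 for a star, 0 for any regular graph; undefined (NaN) below 3 nodes.
    """
    n = net.number_of_nodes()
    if n < 3:
        return math.nan
    degrees = [d for _, d in net.degree()]
    d_max = max(degrees)
    return sum(d_max - d for d in degrees) / ((n - 1) * (n - 2))


def network_summary(net: nx.Graph) -> TopologySummary:
    """Bundle the node/edge counts and the three metrics for one network."""
    apl = average_path_length(net)
    return TopologySummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        clustering_coefficient=clustering_coefficient(net, "global"),
        clustering_coefficient_local=clustering_coefficient(net, "average-local"),
        average_path_length=apl.value,
        excluded_pairs=apl.excluded_pairs,
        centralization=degree_centralization(net),
    )


def summary_table(networks: dict[str, nx.Graph]) -> pd.DataFrame:
    """Multi-network comparison table, one labelled column per network."""
    rows = {name: vars(network_summary(net)) for name, net in networks.items()}
    table = pd.DataFrame(rows)
    table.index.name = "variable"
    return table


def write_report(networks: dict[str, nx.Graph], path) -> None:
    summary_table(networks).to_csv(path, sep="\t")
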