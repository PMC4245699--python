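"""Build the global enzymatic network (GEN) from an EC -> metabolite map.

Two enzymatic activities are connected when they share at least one
metabolite, either as substrate or product. Ubiquitous currency metabolites
(water, ATP, NAD(H), ...) would make almost everything adjacent, so the n
most common metabolites are removed first; the published configuration
filters the 40 most common.

Graphs are :class:`networkx.Graph` objects; every edge carries an
``evidence`` attribute, the frozen set of shared metabolite codes that
justify it.
"""

from __future__ import annotations

import logging
from collections import Counter
from itertools import combinations
from typing import Union

import networkx as nx

from .kegg_ingest import ECMetaboliteMap

logger = logging.getLogger(__name__)


def count_metabolite_frequency(ecmap: ECMetaboliteMap) -> Counter:
    """Count, for each metabolite, the number of distinct ECs using it.

    The count is EC-presence (how many activities touch the metabolite), not
    reaction occurrence; metabolites appearing nowhere are absent.
    """
    counts: Counter = Counter()
    for codes in ecmap.map.values():
        counts.update(codes)
    return counts


def filter_common_metabolites(
    ecmap: ECMetaboliteMap, n: int
) -> tuple[ECMetaboliteMap, list[str]]:
    """Remove the ``n`` most common metabolites from every EC's set.

    Ranking is deterministic: count descending, code ascending; exactly
    ``min(n, vocabulary)`` codes are removed, returned in removal order.
    EC keys are kept even when their set becomes empty, so the node
    inventory of the downstream network is unchanged by filtering.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    counts = count_metabolite_frequency(ecmap)
    ranked = sorted(counts, key=lambda code: (-counts[code], code))
    removed = ranked[:n]
    if n > len(ranked):
        logger.warning("filter n=%d exceeds vocabulary of %d; removing everything", n, len(ranked))
    removed_set = set(removed)
    filtered = {ec: codes - removed_set for ec, codes in ecmap.map.items()}
    return ECMetaboliteMap(map=filtered, provenance=ecmap.provenance), removed


def build_enzyme_network(ecmap: ECMetaboliteMap) -> nx.Graph:
    """Connect two ECs iff their metabolite sets intersect.

    Nodes are all EC keys of the map (ECs emptied by filtering remain as
    isolated nodes); each edge's ``evidence`` attribute holds the shared
    codes. The graph is simple and undirected.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ecmap.map)
    users: dict[str, list[str]] = {}
    for ec, codes in ecmap.map.items():
        for code in codes:
            users.setdefault(code, []).append(ec)
    evidence: dict[tuple[str, str], set[str]] = {}
    for code, ecs in users.items():
        for a, b in combinations(sorted(ecs), 2):
            evidence.setdefault((a, b), set()).add(code)
    for (a, b), codes in evidence.items():
        graph.add_edge(a, b, evidence=frozenset(codes))
    return graph


def drop_isolated(graph: nx.Graph) -> nx.Graph:
    """Return a copy without degree-0 nodes."""
    keep = [n for n in graph if graph.degree(n) > 0]
    return graph.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Edge-list / node-list TSV dialect: one canonical undirected edge per line,
# lexicographically smaller endpoint first, lines sorted.

def write_edge_list(graph: nx.Graph, path, weight: str | None = None) -> None:
    lines = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        if weight is not None:
            lines.append(f"{a}\t{b}\t{data[weight]!r}")  # repr: round-trips exactly
        else:
            lines.append(f"{a}\t{b}")
    with open(path, "w") as fh:
        fh.write("\n".join(sorted(lines)))
        if lines:
            fh.write("\n")


def write_node_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for node in sorted(graph.nodes, key=str):
            fh.write(f"{node}\n")


def read_edge_list(path_or_lines: Union[str, list[str]], weighted: bool = False) -> nx.Graph:
    """Read an edge-list TSV; a third column, when present, becomes the weight."""
    if isinstance(path_or_lines, list):
        lines = path_or_lines
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    graph = nx.Graph()
    for line in lines:
        if not line.strip():
            continue
        parts = line.split("\t")
        if weighted and len(parts) >= 3:
            graph.add_edge(parts[0], parts[1], weight=float(parts[2]))
        else:
            graph.add_edge(parts[0], parts[1])
    return graph


def read_node_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
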