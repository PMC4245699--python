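"""Naive reference implementations used as independent test oracles.

Everything here is written as plainly as possible — double/triple loops,
explicit counting — and stays independent of the code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_shared_metabolite_edges(ecmap: dict[str, set[str]]) -> set[frozenset]:
    """All EC pairs with a non-empty metabolite intersection."""
    edges = set()
    ecs = list(ecmap)
    for i in range(len(ecs)):
        for j in range(i + 1, len(ecs)):
            if ecmap[ecs[i]] & ecmap[ecs[j]]:
                edges.add(frozenset((ecs[i], ecs[j])))
    return edges


def brute_gene_projection(
    gmap: dict[str, set[str]], gen_edges: set[frozenset], same_ec_connect: bool
) -> set[frozenset]:
    """All gene pairs linked through an enzyme-network edge (or a shared EC)."""
    edges = set()
    genes = list(gmap)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            g1, g2 = genes[i], genes[j]
            linked = False
            for a in gmap[g1]:
                for b in gmap[g2]:
                    if a != b and frozenset((a, b)) in gen_edges:
                        linked = True
                    if a == b and same_ec_connect:
                        linked = True
            if linked:
                edges.add(frozenset((g1, g2)))
    return edges


def brute_mutual_information(x, y, bins: int) -> float:
    """Triple-loop plug-in MI in bits over an equal-width grid.

    Binning: floor((v - min) / (max - min) * bins), the maximum pushed into
    the last bin; a constant vector occupies a single bin.
    """

    def bin_of(v, lo, hi, b):
        if hi == lo:
            return 0
        k = int((v - lo) / (hi - lo) * b)
        return b - 1 if k >= b else k

    n = len(x)
    bx = 1 if max(x) == min(x) else bins
    by = 1 if max(y) == min(y) else bins
    counts = [[0] * by for _ in range(bx)]
    for xv, yv in zip(x, y):
        counts[bin_of(xv, min(x), max(x), bins)][bin_of(yv, min(y), max(y), bins)] += 1
    mi = 0.0
    for i in range(bx):
        for j in range(by):
            if counts[i][j] == 0:
                continue
            pij = counts[i][j] / n
            pi = sum(counts[i]) / n
            pj = sum(counts[k][j] for k in range(bx)) / n
            mi += pij * math.log2(pij / (pi * pj))
    return mi


def brute_transitivity(edges: set[frozenset], nodes: list) -> float:
    """3 x triangles / connected triples by explicit enumeration."""
    adj = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    triangles = 0
    for a, b, c in combinations(nodes, 3):
        if b in adj[a] and c in adj[a] and c in adj[b]:
            triangles += 1
    triples = sum(len(adj[n]) * (len(adj[n]) - 1) // 2 for n in nodes)
    if triples == 0:
        return 0.0
    return 3 * triangles / triples


def brute_average_local_clustering(edges: set[frozenset], nodes: list) -> float:
    adj = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    values = []
    for n in nodes:
        k = len(adj[n])
        if k < 2:
            continue
        links = sum(1 for u, v in combinations(adj[n], 2) if v in adj[u])
        values.append(2 * links / (k * (k - 1)))
    return sum(values) / len(values) if values else 0.0


def brute_average_path_length(edges: set[frozenset], nodes: list):
    """Mean BFS distance over connected unordered pairs; (nan, excluded) form."""
    adj = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    total = 0
    connected = 0
    excluded = 0
    for a, b in combinations(nodes, 2):
        # plain BFS from a to b
        frontier, seen, d = [a], {a}, 0
        dist = None
        while frontier:
            if b in frontier:
                dist = d
                break
            d += 1
            frontier = [v for u in frontier for v in adj[u] if v not in seen]
            seen.update(frontier)
        if dist is None:
            excluded += 1
        else:
            total += dist
            connected += 1
    if connected == 0:
        return math.nan, excluded
    return total / connected, excluded


def brute_degree_centralization(edges: set[frozenset], nodes: list) -> float:
    if len(nodes) < 3:
        return math.nan
    degree = {n: 0 for n in nodes}
    for e in edges:
        a, b = tuple(e)
        degree[a] += 1
        degree[b] += 1
    d_max = max(degree.values())
    n = len(nodes)
    return sum(d_max - d for d in degree.values()) / ((n - 1) * (n - 2))
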