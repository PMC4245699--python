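"""Shared fixtures: a seeded synthetic bundle and random-input helpers."""

from __future__ import annotations

import numpy as np
import pytest

from metnetweave import fixtures
from metnetweave.kegg_ingest import ECMetaboliteMap


@pytest.fixture(scope="session")
def bundle() -> fixtures.FixtureBundle:
    """One complete synthetic study reused across test modules."""
    return fixtures.generate_bundle(seed=3)


def random_ec_metabolite_map(rng: np.random.Generator,
                             max_ec: int = 60, max_met: int = 40) -> ECMetaboliteMap:
    """A random EC → metabolite-code map for oracle comparisons."""
    n_ec = int(rng.integers(2, max_ec + 1))
    n_met = int(rng.integers(1, max_met + 1))
    codes = [f"C{i + 1:05d}" for i in range(n_met)]
    mapping = {}
    for i in range(n_ec):
        size = int(rng.integers(0, min(6, n_met) + 1))
        chosen = rng.choice(n_met, size=size, replace=False)
        mapping[f"1.1.1.{i + 1}"] = {codes[int(c)] for c in chosen}
    return ECMetaboliteMap(map=mapping, provenance="union")


def random_graph_edges(rng: np.random.Generator, max_nodes: int = 40):
    """Random simple undirected graph as (nodes, edge set of frozensets)."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = float(rng.uniform(0.05, 0.4))
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add(frozenset((nodes[i], nodes[j])))
    return nodes, edges
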