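"""Combine the organismic enzymatic network with the expression similarity matrix.

The weighted organismic enzymatic network (WOEN) keeps the OEN's metabolic
skeleton and attaches, to every surviving edge, the mutual-information
similarity of its endpoint genes. Genes without expression data carry no
usable weight and are dropped together with their edges — edge existence is
metabolic, the weight is expression-derived, so a zero similarity keeps its
edge (with weight 0) unless the caller asks for pruning.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def weight_network(
    oen: nx.Graph, gesm: pd.DataFrame, min_weight: float | None = None
) -> nx.Graph:
    """Weight the OEN's edges with GESM values (the WOEN).

    Nodes are the intersection of OEN genes and GESM genes; every retained
    edge's ``weight`` is the GESM entry for that pair, bit-for-bit. With
    ``min_weight`` set, edges weighing strictly less are pruned (off by
    default: no weight threshold is applied).
    """
    retained = set(oen.nodes) & set(gesm.index)
    if not retained:
        logger.warning("OEN and GESM share no genes; the weighted network is empty")
    woen = nx.Graph()
    woen.add_nodes_from(retained)
    for g1, g2 in oen.edges:
        if g1 in retained and g2 in retained:
            weight = float(gesm.at[g1, g2])
            if min_weight is not None and weight < min_weight:
                continue
            woen.add_edge(g1, g2, weight=weight)
    return woen
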