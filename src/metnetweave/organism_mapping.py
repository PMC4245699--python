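"""Assign enzymatic activities to organism genes and project the enzyme network.

The homology search compares the reference enzyme sequences of each EC number
(the gold-standard enzymes, used as queries) against the organism's
protein-coding genes (subjects). Its 12-column tabular output is parsed here;
hits passing the E-value threshold (default 1e-5, inclusive) annotate genes
with EC numbers, and the enzyme network (GEN) is then projected onto the gene
set: two genes are linked when their ECs are linked in the GEN — the
organismic enzymatic network (OEN).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, TextIO, Union

import networkx as nx
import pandas as pd

from .kegg_ingest import EC_PATTERN, _as_lines

logger = logging.getLogger(__name__)

#: Marker used in edge support when two genes are linked because they share
#: an EC number (isozymes), rather than through a GEN edge.
SAME_EC = "same-ec"

_QUERY_PATTERN = re.compile(r"^(?:ec:)?([^|]+)\|(.*)$")

DEFAULT_EVALUE = 1e-5


@dataclass
class HomologyHit:
    """One tabular homology hit: a reference enzyme (tagged with its EC) vs a gene."""

    ec: str
    ref_id: str
    subject_gene: str
    identity_pct: float
    evalue: float
    bitscore: float


@dataclass
class GeneECMap:
    """Gene ID -> non-empty set of EC numbers, from thresholded homology hits."""

    map: dict[str, set[str]] = field(default_factory=dict)
    threshold_used: float = DEFAULT_EVALUE


def parse_homology_hits(
    stream: Union[str, TextIO, Iterable[str]], swap: bool = False
) -> list[HomologyHit]:
    """Parse 12-column tabular homology output.

    Columns follow the standard convention (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore); the query ID
    encodes the EC tag as ``ec:<EC>|<seqid>``. ``swap=True`` handles runs
    made in the reverse orientation (organism protein as query). Lines with
    an unparseable EC tag are skipped with a warning; a wrong column count is
    a parse error naming the line.
    """
    hits: list[HomologyHit] = []
    skipped = 0
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(cols)}")
        tagged, gene = (cols[1], cols[0]) if swap else (cols[0], cols[1])
        match = _QUERY_PATTERN.match(tagged)
        if not match or not EC_PATTERN.match(match.group(1)):
            skipped += 1
            continue
        hits.append(
            HomologyHit(
                ec=match.group(1),
                ref_id=match.group(2),
                subject_gene=gene,
                identity_pct=float(cols[2]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
            )
        )
    if skipped:
        logger.warning("%d hit lines skipped (unparseable EC tag)", skipped)
    return hits


def assign_ec_to_genes(hits: list[HomologyHit], threshold: float = DEFAULT_EVALUE) -> GeneECMap:
    """Annotate genes with every EC supported by a hit with evalue <= threshold.

    Genes with no passing hit are absent; a gene may carry several ECs.
    Thresholding is inclusive. The result is independent of hit order and of
    any chunking of the input file.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gmap: dict[str, set[str]] = {}
    for hit in hits:
        if hit.evalue <= threshold:
            gmap.setdefault(hit.subject_gene, set()).add(hit.ec)
    return GeneECMap(map=gmap, threshold_used=threshold)


def project_gene_network(
    gmap: GeneECMap, gen: nx.Graph, same_ec_policy: str = "connect"
) -> nx.Graph:
    """Project the enzyme network onto the organism's gene set (the OEN).

    Genes g1 != g2 are connected iff some pair of their ECs is an edge of the
    GEN, or (policy "connect") they share an EC outright — isozymes share all
    of that activity's metabolites, so the GEN's no-self-loop convention
    should not disconnect them. Every edge carries a ``support`` attribute:
    the witnessing EC pairs (canonically ordered) and/or the same-EC marker.
    ECs absent from the GEN are dropped with a warning. Nodes are all genes
    of the map.
    """
    if same_ec_policy not in ("connect", "ignore"):
        raise ValueError(f"same_ec_policy must be 'connect' or 'ignore', got {same_ec_policy!r}")
    known = set(gen.nodes)
    unknown = {ec for ecs in gmap.map.values() for ec in ecs} - known
    if unknown:
        logger.warning("%d ECs in the gene map are absent from the GEN and are ignored", len(unknown))
    oen = nx.Graph()
    oen.add_nodes_from(gmap.map)
    by_ec: dict[str, list[str]] = {}
    for gene, ecs in gmap.map.items():
        for ec in ecs & known:
            by_ec.setdefault(ec, []).append(gene)
    support: dict[tuple[str, str], set] = {}
    for a, b in gen.edges:
        for g1, g2 in product(by_ec.get(a, ()), by_ec.get(b, ())):
            if g1 == g2:
                continue
            key = (g1, g2) if g1 < g2 else (g2, g1)
            support.setdefault(key, set()).add((a, b) if a < b else (b, a))
    if same_ec_policy == "connect":
        for ec, genes in by_ec.items():
            for g1, g2 in combinations(sorted(genes), 2):
                support.setdefault((g1, g2), set()).add(SAME_EC)
    for (g1, g2), witnesses in support.items():
        oen.add_edge(g1, g2, support=frozenset(witnesses))
    return oen


def to_adjacency_matrix(net: nx.Graph, weight: str | None = None) -> pd.DataFrame:
    """Symmetric adjacency matrix with genes sorted ascending; diagonal 0.

    Binary when ``weight`` is None, otherwise the named edge attribute.
    Only genes present in the network appear — genes that could not be
    annotated upstream are simply not rows of the matrix.
    """
    index = sorted(net.nodes, key=str)
    mat = nx.to_pandas_adjacency(net, nodelist=index, weight=weight, dtype=float)
    if weight is None:
        mat = (mat > 0).astype(int)
    return mat


def from_adjacency_matrix(mat: pd.DataFrame, weighted: bool = False) -> nx.Graph:
    """Inverse of :func:`to_adjacency_matrix` (round-trip identity)."""
    graph = nx.Graph()
    graph.add_nodes_from(mat.index)
    for i, gi in enumerate(mat.index):
        for j in range(i + 1, len(mat.index)):
            gj = mat.index[j]
            value = mat.iloc[i, j]
            if value != 0:
                if weighted:
                    graph.add_edge(gi, gj, weight=float(value))
                else:
                    graph.add_edge(gi, gj)
    return graph


def write_gene_ec_list(gmap: GeneECMap, path) -> None:
    """Two-column TSV (EC, gene), the 'Blasted_genes.list' dialect."""
    rows = sorted((ec, gene) for gene, ecs in gmap.map.items() for ec in ecs)
    with open(path, "w") as fh:
        for ec, gene in rows:
            fh.write(f"{ec}\t{gene}\n")


def read_gene_ec_list(stream: Union[str, TextIO, Iterable[str]],
                      threshold: float = DEFAULT_EVALUE) -> GeneECMap:
    gmap: dict[str, set[str]] = {}
    for line in _as_lines(stream):
        if not line.strip():
            continue
        ec, gene = line.split("\t")[:2]
        gmap.setdefault(gene, set()).add(ec)
    return GeneECMap(map=gmap, threshold_used=threshold)


def write_adjacency_tsv(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="")


def read_adjacency_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
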