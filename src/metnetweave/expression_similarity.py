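"""Probe collapsing, dataset intersection and the mutual-information similarity matrix.

Expression matrices are pandas DataFrames with genes as rows (unique index)
and samples as columns, assumed already normalized and log2-transformed
upstream. Pairwise gene similarity is the plug-in mutual information
estimate, in bits, over an equal-width binned joint histogram — the gene
expression similarity matrix (GESM) used to weight the organismic network.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_genes: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Collapse a probes x samples table to genes x samples.

    Probes mapping to more than one gene are discarded outright (their signal
    is ambiguous); probes absent from the mapping are dropped with a warning.
    When several probes remain for a gene, the probe with the highest mean
    value across samples represents it — one coherent profile, rather than a
    per-sample max that would chimerize profiles. Genes with no surviving
    probe are absent; rows are sorted by gene ID.
    """
    unmapped = [p for p in probe_values.index if p not in probe_to_genes]
    if unmapped:
        logger.warning("%d probes absent from the probe map were dropped", len(unmapped))
    best: dict[str, tuple[float, str]] = {}
    for probe in probe_values.index:
        genes = probe_to_genes.get(probe)
        if genes is None or len(genes) != 1:
            continue
        (gene,) = genes
        mean = float(probe_values.loc[probe].mean())
        if gene not in best or mean > best[gene][0]:
            best[gene] = (mean, probe)
    genes = sorted(best)
    out = probe_values.loc[[best[g][1] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return out


def read_probe_map(path_or_lines) -> dict[str, set[str]]:
    """Two-column TSV (probe, gene); repeated probe lines mark multi-gene probes."""
    if isinstance(path_or_lines, list):
        lines = path_or_lines
    else:
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    mapping: dict[str, set[str]] = {}
    for line in lines:
        if not line.strip():
            continue
        probe, gene = line.split("\t")[:2]
        mapping.setdefault(probe, set()).add(gene)
    return mapping


def intersect_datasets(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Restrict to genes common to all datasets and concatenate samples.

    Sample IDs are prefixed with a dataset ordinal (``d0.``, ``d1.``, ...) so
    collisions across series cannot occur. Genes are sorted ascending; an
    empty intersection is an error — there is nothing left to analyze.
    """
    if not matrices:
        raise ValueError("need at least one expression matrix")
    common = set(matrices[0].index)
    for mat in matrices[1:]:
        common &= set(mat.index)
    if not common:
        raise ValueError("no gene is common to all datasets")
    genes = sorted(common)
    parts = []
    for i, mat in enumerate(matrices):
        part = mat.loc[genes].copy()
        part.columns = [f"d{i}.{c}" for c in mat.columns]
        parts.append(part)
    out = pd.concat(parts, axis=1)
    out.index.name = "gene"
    return out


def _bin_indices(values: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Equal-width bin index of each value over the observed range.

    index = floor((v - lo) / (hi - lo) * bins), the maximum clipped into the
    last bin; a zero-range vector collapses to a single bin.
    """
    lo = values.min()
    hi = values.max()
    if hi == lo:
        return np.zeros(values.shape[0], dtype=np.intp), 1
    idx = ((values - lo) / (hi - lo) * bins).astype(np.intp)
    np.clip(idx, 0, bins - 1, out=idx)
    return idx, bins


def mutual_information(x, y, bins: int) -> float:
    """Plug-in mutual information of two real vectors, in bits.

    MI = sum_ij p_ij log2(p_ij / (p_i. p_.j)) over a bins x bins equal-width
    grid spanning each vector's observed range. Symmetric in (x, y) and
    non-negative (tiny negative rounding is clamped to 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.shape[0] < 2:
        raise ValueError("need at least two observations")
    if bins < 1:
        raise ValueError("bins must be a positive integer")
    ix, bx = _bin_indices(x, bins)
    iy, by = _bin_indices(y, bins)
    joint = np.bincount(ix * by + iy, minlength=bx * by).reshape(bx, by) / x.shape[0]
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)


def sturges_bins(n_samples: int) -> int:
    """Sturges' rule: ceil(log2(S) + 1) bins for S samples."""
    return int(math.ceil(math.log2(n_samples) + 1))


def build_similarity_matrix(expr: pd.DataFrame, bins: int | str = "auto") -> pd.DataFrame:
    """Symmetric gene x gene mutual-information matrix (the GESM).

    Each unordered pair is computed once and mirrored, so the matrix equals
    its transpose exactly. The diagonal is stored as 0 by convention:
    self-information would dominate any weight scale and is never consumed
    downstream. ``bins="auto"`` applies Sturges' rule to the sample count.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least two genes")
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    n_bins = sturges_bins(expr.shape[1]) if bins == "auto" else int(bins)
    genes = list(expr.index)
    values = expr.to_numpy(dtype=float)
    n = values.shape[1]
    # bin each gene's profile once; pairwise joint histograms via bincount
    indexed = [_bin_indices(values[i], n_bins) for i in range(len(genes))]
    out = np.zeros((len(genes), len(genes)))
    for i, j in combinations(range(len(genes)), 2):
        ix, bx = indexed[i]
        iy, by = indexed[j]
        joint = np.bincount(ix * by + iy, minlength=bx * by).reshape(bx, by) / n
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))
        out[i, j] = out[j, i] = max(mi, 0.0)
    return pd.DataFrame(out, index=genes, columns=genes)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index.name = "gene"
    return mat


def write_similarity_tsv(gesm: pd.DataFrame, path) -> None:
    gesm.to_csv(path, sep="\t", index_label="")


def read_similarity_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
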