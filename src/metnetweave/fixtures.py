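"""Self-contained synthetic inputs with known ground truth.

Every pipeline stage needs an input dialect (compound flat file, enzyme
entries, tabular homology hits, probe-level expression) and every test needs
the exact expected result. The generators here produce both at once: valid
text in the dialects the parsers read, plus the truth objects (enzyme
network before and after currency filtering, gene→EC map, module labels)
computed directly from the sampled assignment, so recovery can be asserted
exactly.

Design: currency metabolites attach to every enzyme, so filtering the
``n_currency`` most common codes disconnects exactly them; non-currency
metabolites are shared between enzyme pairs with a given density from a
disjoint pool (private metabolites are unique per enzyme, so zero density
means zero post-filter edges). Expression follows a per-module latent
factor model: within-module correlation ``rho_within``, zero expected
correlation between modules.

All randomness flows from one integer seed through ``numpy``'s Generator;
regenerating with the same seed reproduces every field byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import gen_builder, organism_mapping
from .expression_similarity import write_expression_tsv
from .kegg_ingest import ECMetaboliteMap
from .organism_mapping import GeneECMap


@dataclass
class FixtureBundle:
    """One coherent synthetic study: raw texts plus their ground truth."""

    compound_text: str = ""
    enzyme_text: str = ""
    truth_map: ECMetaboliteMap | None = None          # pre-filter EC -> codes
    truth_network: object = None                      # post-filter enzyme network
    truth_network_prefilter: object = None
    currency: list[str] = field(default_factory=list)
    filter_n: int = 0
    truth_gene_map: GeneECMap | None = None
    hits_text: str = ""
    expression: list[pd.DataFrame] = field(default_factory=list)
    probe_tables: list[pd.DataFrame] = field(default_factory=list)
    probe_map: dict[str, set[str]] = field(default_factory=dict)
    module_assignment: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def _ec_numbers(n: int) -> list[str]:
    return [f"{(i % 6) + 1}.{(i % 4) + 1}.{(i % 3) + 1}.{i + 1}" for i in range(n)]


def _names_for(i: int) -> tuple[str, str]:
    return f"met{i}", f"Metabolite {i}"


def _compound_text(codes: list[str]) -> str:
    blocks = []
    for code in codes:
        i = int(code[1:])
        primary, synonym = _names_for(i)
        blocks.append(
            f"ENTRY       {code}                      Compound\n"
            f"NAME        {primary};\n"
            f"            {synonym}\n"
            "///"
        )
    return "\n".join(blocks) + ("\n" if blocks else "")


def _spell(code: str, rng: np.random.Generator) -> str:
    """Spell a metabolite as one of its names, varying case, or as its code."""
    i = int(code[1:])
    primary, synonym = _names_for(i)
    choice = rng.integers(0, 4)
    name = (primary, synonym, primary.upper(), code)[choice]
    if choice < 3 and rng.random() < 0.2:
        name = f"2 {name}"  # stoichiometric coefficient, stripped by the parser
    return name


def _equation(codes: list[str], rng: np.random.Generator) -> str:
    spelled = [_spell(c, rng) for c in codes]
    if len(spelled) == 1:
        return f"{spelled[0]} <=> {spelled[0]}"
    half = max(1, len(spelled) // 2)
    return " + ".join(spelled[:half]) + " <=> " + " + ".join(spelled[half:])


def _enzyme_text(ecs: list[str], assignment: dict[str, set[str]],
                 rng: np.random.Generator) -> str:
    blocks = []
    for k, ec in enumerate(ecs):
        codes = sorted(assignment[ec])
        lines = [f"ENTRY       EC {ec}                 Enzyme",
                 f"NAME        enzyme-{k + 1}"]
        if codes:
            # occasionally split into a main reaction plus a variant so the
            # "main" summarization mode is a proper subset of "union"
            if len(codes) >= 4 and rng.random() < 0.5:
                cut = len(codes) // 2
                reactions = [_equation(codes[:cut], rng), _equation(codes[cut:], rng)]
            else:
                reactions = [_equation(codes, rng)]
            lines.append(f"REACTION    {reactions[0]}")
            for extra in reactions[1:]:
                lines.append(f"            ;{extra}")
        lines.append("///")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + ("\n" if blocks else "")


def generate_toy_kegg(
    n_ec: int,
    n_metabolites: int,
    n_currency: int,
    sharing_density: float,
    seed: int,
) -> FixtureBundle:
    """Generate compound + enzyme texts with exact pre/post-filter truth networks.

    Currency metabolites (the first ``n_currency`` codes) attach to every
    enzyme; each enzyme pair shares a fresh pool metabolite with probability
    ``sharing_density``; leftover pool metabolites are private (one enzyme
    each). The truth networks are built from the realized assignment, so
    they are exact even if the pool is exhausted and codes get reused.
    """
    if n_currency > n_metabolites:
        raise ValueError("n_currency cannot exceed n_metabolites")
    if not 0 <= sharing_density <= 1:
        raise ValueError("sharing_density must be in [0, 1]")
    if n_ec < 0 or n_metabolites < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    ecs = _ec_numbers(n_ec)
    codes = [f"C{i + 1:05d}" for i in range(n_metabolites)]
    currency = codes[:n_currency]
    pool = codes[n_currency:]
    assignment: dict[str, set[str]] = {ec: set(currency) for ec in ecs}

    ptr = 0
    shared_used: list[str] = []
    for a, b in combinations(ecs, 2):
        if rng.random() < sharing_density:
            if ptr < len(pool):
                code = pool[ptr]
                ptr += 1
                shared_used.append(code)
            elif shared_used:
                code = shared_used[int(rng.integers(0, len(shared_used)))]
            else:
                continue
            assignment[a].add(code)
            assignment[b].add(code)
    if n_ec:
        for k, code in enumerate(pool[ptr:]):  # private: one enzyme per metabolite
            assignment[ecs[k % n_ec]].add(code)

    truth_map = ECMetaboliteMap(map={ec: set(s) for ec, s in assignment.items()},
                                provenance="union")
    prefilter = gen_builder.build_enzyme_network(truth_map)
    filtered, _ = gen_builder.filter_common_metabolites(truth_map, n_currency)
    postfilter = gen_builder.build_enzyme_network(filtered)

    return FixtureBundle(
        compound_text=_compound_text(codes),
        enzyme_text=_enzyme_text(ecs, assignment, rng),
        truth_map=truth_map,
        truth_network=postfilter,
        truth_network_prefilter=prefilter,
        currency=list(currency),
        filter_n=n_currency,
        seed=seed,
    )


def generate_toy_homology(
    truth_gene_map: GeneECMap, decoy_rate: float, seed: int
) -> str:
    """Emit 12-column tabular homology hits encoding a known gene→EC truth.

    Every truth (EC, gene) pair gets a hit with evalue <= 1e-8; decoys (pairs
    outside the truth) get evalue in [1e-3, 1e-2] at ``decoy_rate`` relative
    to the truth count. Thresholding at 1e-5 therefore recovers the truth
    exactly, while a loose 1e-2 threshold admits every decoy.
    """
    if not 0 <= decoy_rate < 1:
        raise ValueError("decoy_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth_pairs = sorted(
        (ec, gene) for gene, ecs in truth_gene_map.map.items() for ec in ecs
    )

    def hit_line(ec: str, gene: str, idx: int, strong: bool) -> str:
        length = int(rng.integers(80, 400))
        pident = round(float(rng.uniform(60, 99)), 1)
        mismatch = int(rng.integers(0, 40))
        exponent = int(rng.integers(9, 21)) if strong else 3
        mantissa = round(float(rng.uniform(1.0, 9.9)), 1)
        evalue = f"{mantissa}e-{exponent:02d}"
        bitscore = round(float(rng.uniform(50, 500)), 1)
        return "\t".join(
            [f"ec:{ec}|ref{idx:04d}", gene, str(pident), str(length), str(mismatch),
             "0", "1", str(length), "1", str(length), evalue, str(bitscore)]
        )

    lines = [hit_line(ec, gene, i, strong=True)
             for i, (ec, gene) in enumerate(truth_pairs)]
    truth_set = set(truth_pairs)
    ecs = sorted({ec for ec, _ in truth_pairs})
    genes = sorted(truth_gene_map.map)
    n_decoys = round(decoy_rate * len(truth_pairs))
    made = 0
    attempts = 0
    while made < n_decoys and attempts < 50 * max(n_decoys, 1) and ecs:
        attempts += 1
        ec = ecs[int(rng.integers(0, len(ecs)))]
        if rng.random() < 0.5 and genes:
            gene = genes[int(rng.integers(0, len(genes)))]
        else:
            gene = f"DECOY{int(rng.integers(0, 10 * max(n_decoys, 1))):04d}"
        if (ec, gene) in truth_set:
            continue
        lines.append(hit_line(ec, gene, len(truth_pairs) + made, strong=False))
        made += 1
    order = rng.permutation(len(lines))
    return "\n".join(lines[i] for i in order) + ("\n" if lines else "")


def generate_expression_data(
    genes: list[str],
    modules: dict[str, str],
    n_samples: int,
    rho_within: float,
    seed: int,
) -> pd.DataFrame:
    """Per-module latent factor model on the log2 scale.

    Each gene's profile is sqrt(rho_within) x its module's factor plus
    sqrt(1 - rho_within) x private noise, all components standard normal, so
    the expected within-module correlation is rho_within and the expected
    between-module correlation is 0.
    """
    if not 0 <= rho_within < 1:
        raise ValueError("rho_within must be in [0, 1)")
    if genes and n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    samples = [f"S{j:03d}" for j in range(n_samples)]
    if not genes:
        return pd.DataFrame(index=pd.Index([], name="gene"), columns=samples, dtype=float)
    labels = sorted({modules[g] for g in genes})
    factors = {m: rng.standard_normal(n_samples) for m in labels}
    rows = np.empty((len(genes), n_samples))
    a = np.sqrt(rho_within)
    b = np.sqrt(1.0 - rho_within)
    for i, gene in enumerate(genes):
        rows[i] = a * factors[modules[gene]] + b * rng.standard_normal(n_samples)
    out = pd.DataFrame(rows, index=pd.Index(list(genes), name="gene"), columns=samples)
    return out


def to_probe_level(
    expr: pd.DataFrame, seed: int, n_multigene_decoys: int = 2
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Wrap a gene-level matrix into probes with a probe→gene map.

    Each gene gets a primary probe carrying its exact profile and, for some
    genes, a secondary probe shifted down by ~1 log2 unit (so the max-mean
    collapse rule recovers the primary rows exactly). A few decoy probes map
    to two genes and must be discarded by the collapse step.
    """
    rng = np.random.default_rng(seed)
    rows = []
    names = []
    mapping: dict[str, set[str]] = {}
    for gene in expr.index:
        primary = f"{gene}_at"
        rows.append(expr.loc[gene].to_numpy())
        names.append(primary)
        mapping[primary] = {gene}
        if rng.random() < 0.5:
            secondary = f"{gene}_x_at"
            rows.append(expr.loc[gene].to_numpy() - 1.0
                        + 0.05 * rng.standard_normal(expr.shape[1]))
            names.append(secondary)
            mapping[secondary] = {gene}
    gene_list = list(expr.index)
    for d in range(min(n_multigene_decoys, max(len(gene_list) - 1, 0))):
        probe = f"multi{d}_s_at"
        rows.append(rng.standard_normal(expr.shape[1]) + 5.0)  # high signal, ambiguous
        names.append(probe)
        mapping[probe] = {gene_list[d], gene_list[d + 1]}
    table = pd.DataFrame(rows, index=pd.Index(names, name="probe"), columns=expr.columns)
    return table, mapping


def generate_bundle(
    n_ec: int = 12,
    n_metabolites: int = 60,
    n_currency: int = 3,
    sharing_density: float = 0.25,
    max_genes_per_ec: int = 3,
    n_modules: int = 3,
    n_samples: int = 60,
    rho_within: float = 0.9,
    decoy_rate: float = 0.3,
    n_datasets: int = 2,
    dropout_genes: int = 2,
    seed: int = 0,
) -> FixtureBundle:
    """Compose a complete synthetic study covering every pipeline stage.

    ``dropout_genes`` genes are omitted from the later expression datasets,
    so the common-gene intersection (and hence the weighted network) is a
    strict shrinkage of the projected gene network, mirroring how genes
    without expression data drop out of the final weighted stage.
    """
    rng = np.random.default_rng(seed)
    subseeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    bundle = generate_toy_kegg(n_ec, n_metabolites, n_currency, sharing_density,
                               seed=subseeds[0])
    bundle.seed = seed

    # fan each EC out to 1..max_genes_per_ec organism genes
    grng = np.random.default_rng(subseeds[1])
    ecs = sorted(bundle.truth_map.map)
    pool = [f"AT{(i % 5) + 1}G{(i + 1) * 10:05d}" for i in range(2 * n_ec)]
    gmap: dict[str, set[str]] = {}
    for ec in ecs:
        k = int(grng.integers(1, max_genes_per_ec + 1))
        chosen = grng.choice(len(pool), size=min(k, len(pool)), replace=False)
        for idx in chosen:
            gmap.setdefault(pool[int(idx)], set()).add(ec)
    bundle.truth_gene_map = GeneECMap(map=gmap, threshold_used=1e-5)
    bundle.hits_text = generate_toy_homology(bundle.truth_gene_map, decoy_rate,
                                             seed=subseeds[2])

    genes = sorted(gmap)
    mrng = np.random.default_rng(subseeds[3])
    bundle.module_assignment = {
        g: f"M{int(mrng.integers(0, n_modules))}" for g in genes
    }
    for d in range(n_datasets):
        keep = list(genes)
        if d > 0 and dropout_genes:
            drop = mrng.choice(len(genes), size=min(dropout_genes, len(genes) - 2),
                               replace=False)
            dropped = {genes[int(i)] for i in drop}
            keep = [g for g in genes if g not in dropped]
        expr = generate_expression_data(keep, bundle.module_assignment, n_samples,
                                        rho_within, seed=subseeds[4] + d)
        bundle.expression.append(expr)
        probes, pmap = to_probe_level(expr, seed=subseeds[5] + d)
        bundle.probe_tables.append(probes)
        bundle.probe_map.update(pmap)
    return bundle


def write_bundle(bundle: FixtureBundle, outdir) -> list[Path]:
    """Write every bundle artifact in the dialects the other modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def text(name: str, content: str) -> None:
        path = outdir / name
        path.write_text(content)
        written.append(path)

    text("compounds.txt", bundle.compound_text)
    text("enzymes.txt", bundle.enzyme_text)
    text("hits.tsv", bundle.hits_text)
    if bundle.truth_network is not None:
        gen_builder.write_edge_list(bundle.truth_network, outdir / "truth_gen_edges.tsv")
        written.append(outdir / "truth_gen_edges.tsv")
    if bundle.truth_gene_map is not None:
        organism_mapping.write_gene_ec_list(bundle.truth_gene_map,
                                            outdir / "truth_gene_ec.tsv")
        written.append(outdir / "truth_gene_ec.tsv")
    for d, probes in enumerate(bundle.probe_tables):
        path = outdir / f"probes_d{d}.tsv"
        probes.to_csv(path, sep="\t", index_label="probe")
        written.append(path)
    for d, expr in enumerate(bundle.expression):
        path = outdir / f"expr_d{d}.tsv"
        write_expression_tsv(expr, path)
        written.append(path)
    if bundle.probe_map:
        lines = sorted(f"{p}\t{g}" for p, gs in bundle.probe_map.items() for g in gs)
        text("probe_map.tsv", "\n".join(lines) + "\n")
    if bundle.module_assignment:
        lines = sorted(f"{g}\t{m}" for g, m in bundle.module_assignment.items())
        text("modules.tsv", "\n".join(lines) + "\n")
    return written
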