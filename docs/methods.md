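# Methods

## Model

The package reconstructs gene interaction networks in three stages, each a
pure function of plain-text inputs.

**Enzyme network (GEN).** From compound and enzyme flat files we build an
EC → metabolite-code map, then connect two EC numbers whenever their sets
intersect. Reaction direction is discarded throughout: an activity touches a
metabolite "as substrate or product", so substrates and products are pooled
per reaction before summarization. Each EC may carry several reaction
variants; the default summarization (`mode="union"`) pools all variants, and
`mode="main"` keeps only the first-listed reaction. Union maximizes recall
and leaves currency filtering as the sole sparsifier; both interpretations
are exposed because the per-EC "main reaction" convention is ambiguous in
practice, and the main-mode map is provably EC-wise a subset of the union
map.

**Currency filtering.** Ubiquitous metabolites would make the graph nearly
complete, so the *n* most common (counted as the number of distinct ECs
whose set contains the metabolite, after summarization) are removed from
every set before linking. Ranking is strictly deterministic — count
descending, code ascending — and exactly *n* codes are removed, never "all
tied at rank n": reproducibility of the network across runs outweighs any
argument for tie-expansion. ECs emptied by filtering remain as isolated
nodes so the node inventory matches the EC inventory; `drop_isolated` (or
`--drop-isolated`) removes them on request. The published configuration
filters the 40 most common metabolites; fixture-scale runs filter exactly
their planted currency set.

**Gene projection (OEN).** 12-column tabular homology hits (reference
enzyme tagged `ec:<EC>|<seqid>` as query, organism protein as subject;
`--swap` for the reverse orientation) assign ECs to genes at an inclusive
E-value threshold, default 1e-5. Two genes are linked when some pair of
their ECs is a GEN edge. Genes annotated to the *same* EC are linked by
default (`same_ec_policy="connect"`): isozymes share all of that activity's
metabolites, and only the no-self-loop convention of the enzyme graph would
otherwise disconnect them; `"ignore"` implements the stricter reading.
Assignment and projection are order- and chunking-independent, so hit files
produced by parallel subset runs concatenate safely.

**Expression similarity (GESM).** Expression matrices are consumed already
normalized and log2-transformed (RMA/quantile normalization is upstream
scope). Probes mapping to more than one gene are discarded; among a gene's
remaining probes, the one with the highest mean across samples represents it
— a single coherent profile rather than a per-sample max, which would
chimerize profiles (the literal per-sample alternative is available as a
flagged variant of the design, not the default). Datasets are intersected on
common genes, with sample IDs prefixed by dataset ordinal. Pairwise
similarity is plug-in mutual information in bits on an equal-width
`bins × bins` grid spanning each vector's observed range; bin index is
`floor((v - lo)/(hi - lo) * bins)` with the maximum clipped into the last
bin and a zero-range vector collapsing to one bin. Default bin count is
Sturges' rule, ⌈log₂(S)+1⌉ for S samples. MI is not normalized to [0, 1]
(raw bits are the weight currency) and the diagonal is stored as 0:
self-information H(X) would dominate any weight scale and is never consumed
downstream. Equal-width plug-in estimation is the canonical microarray-era
choice; the estimator sits behind a single function so alternatives
(equal-frequency, shrinkage) can be added without touching callers.

**Weighting (WOEN).** Nodes are the intersection of OEN genes and GESM
genes; genes without expression data are dropped with their edges, and every
surviving edge carries the GESM entry bit-for-bit. Zero-similarity edges are
kept — edge existence is metabolic, the weight is expression-derived — and
no weight threshold or renormalization is applied by default (`min_weight`
exists for users who want pruning).

**Topology.** Each network is summarized by node/edge counts, clustering
coefficient, average path length and Freeman degree centralization
Σᵢ(d_max−dᵢ)/((n−1)(n−2)). Clustering defaults to global transitivity
(3·triangles / connected triples) with the average-local variant (mean local
clustering over nodes of degree ≥ 2) reported alongside, since either
convention is common in network libraries. Average path length is the mean
over *connected* unordered pairs, with the count of excluded
(cross-component) pairs surfaced rather than penalized — the conventional
choice for graphs with isolates. Undefined cases (path length with no
connected pair, centralization below 3 nodes) are NaN.

## Synthetic data generator

`metnetweave.fixtures` emulates the statistical shape of the three input
kinds, with ground truth carried alongside the raw text:

* **KEGG part** — currency metabolites attach to every enzyme, so filtering
  the `n_currency` most common codes disconnects exactly them; non-currency
  metabolites are shared between enzyme pairs with probability
  `sharing_density` from a disjoint pool, and leftover pool codes are
  private (one enzyme each), so zero density yields zero post-filter edges.
  Truth networks are recomputed from the realized assignment, making them
  exact even under pool reuse. Reaction text spells metabolites variously as
  primary name, synonym, upper-case variant or code, with occasional
  stoichiometric coefficients, to exercise normalization and resolution.
* **Homology part** — every planted (EC, gene) pair appears with
  E ≤ 10⁻⁸; decoy pairs (at `decoy_rate` relative to truth) appear with
  E ∈ [10⁻³, 10⁻²], so the 10⁻⁵ threshold recovers the planted map exactly
  while a loose 10⁻² threshold admits every decoy.
* **Expression part** — a per-module latent factor model on the log2 scale:
  gene value = √ρ·module factor + √(1−ρ)·noise with standard-normal
  components, giving expected within-module correlation ρ (`rho_within`,
  default 0.9 for planted-recovery checks) and expected between-module
  correlation 0. Gene-level rows are wrapped into probes (primary probe
  exact, optional secondary probe ~1 log2 unit lower, a few two-gene decoy
  probes) so the collapse step is exercised end to end.

All randomness flows from a single integer seed through numpy Generators
(sub-seeds for each part), so regeneration is byte-identical — the
foundation of the determinism tests.

What the generator does **not** emulate: Affymetrix CEL structure and RMA
artifacts, KEGG record quirks beyond what the parsers consume, realistic
degree distributions (no scale-free structure is planted), batch effects, or
non-Gaussian expression noise. Passing tests therefore demonstrate
correctness of the graph and estimator algebra on inputs of the right shape,
not robustness to real microarray pathology.

## Defaults that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| filter `n` | 40 (CLI) | metabolites | published configuration for the global network |
| E-value threshold | 1e-5, inclusive | — | published choice; inclusive comparison is conventional |
| `same_ec_policy` | connect | — | isozymes share a full metabolite set |
| MI bins | Sturges ⌈log₂S+1⌉ | bins/axis | standard density-estimation default at microarray sample sizes |
| MI base | log₂ (bits) | bits | interpretable weight currency |
| `rho_within` | 0.9 | correlation | strong planted signal for recovery checks |
| fixture sizes | ≤ 50 ECs, ≤ 100 genes, ≤ 200 samples | — | full suite runs in seconds |

The acceptance script runs a 30-EC / 160-metabolite / 5-currency study with
~40 genes, two 200-sample expression datasets and 3 planted modules — large
enough for stable topology and MI contrast, small enough to finish in
seconds.

## Numerical notes

* MI symmetry in (x, y) holds to float summation order (the joint histogram
  transposes); the similarity matrix itself is exactly symmetric because
  each pair is computed once and mirrored. Tiny negative MI from rounding is
  clamped to 0.
* Edge lists are written canonically (lexicographically smaller endpoint
  first, sorted lines) and weights with `repr`, so write→read round-trips
  are exact.
* Duplicate synonym collisions in compound files resolve to the first
  occurrence with a logged warning; silent override would corrupt audits.
* Degenerate inputs: empty maps/networks propagate as empty results; an
  empty gene intersection across expression datasets is an error (nothing to
  analyze); a disjoint OEN/GESM gene set yields an empty weighted network
  with a warning.

## Limitations

* No stoichiometry, reversibility or pathway-aware linking; the enzyme graph
  is purely shared-metabolite.
* A single E-value threshold — no reciprocal-best-hit, coverage or identity
  filters.
* The currency list is recomputed from the input's own frequencies, never
  hard-coded from any snapshot, so networks built from different database
  versions will differ.
* Live database download and the homology search itself are out of scope;
  the package consumes their file outputs.
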