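# metnetweave

Reconstruction of gene interaction networks from enzymatic-reaction data and
gene expression, for systems biologists who want a metabolic scaffold for
coexpression analysis in any organism with genomic data.

The pipeline has three stages:

1. **Global enzymatic network (GEN).** Nodes are Enzyme Commission (EC)
   numbers; two activities are linked when they share at least one
   metabolite, as substrate or product. Because currency metabolites (H₂O,
   ATP, NAD(H), ...) take part in very many reactions and would over-connect
   the graph, the *n* most common metabolites are removed first (the
   published configuration uses *n* = 40).
2. **Organismic enzymatic network (OEN).** The reference enzyme sequences of
   each EC are compared against the organism's protein-coding genes by a
   BLASTP-style homology search; hits with E ≤ 10⁻⁵ assign EC numbers to
   genes, and two genes are linked when their ECs are linked in the GEN.
3. **Weighted OEN (WOEN).** Gene expression profiles (probe-collapsed,
   intersected across datasets) yield a gene expression similarity matrix
   (GESM) of pairwise mutual information,
   MI(X,Y) = Σᵢⱼ p̂ᵢⱼ log₂ ( p̂ᵢⱼ / (p̂ᵢ· p̂·ⱼ) ) bits,
   estimated from an equal-width binned joint histogram. Each OEN edge is
   weighted by the MI of its endpoints; genes without expression data drop
   out.

Every stage reports the same topological summary — node and edge counts,
clustering coefficient (transitivity), average shortest-path length over
connected pairs, and Freeman degree centralization
Σᵢ(d_max − dᵢ)/((n−1)(n−2)) — so the effect of each transformation is
visible as a change in network shape.

All inputs and outputs are plain text: KEGG-style compound/enzyme flat
files, 12-column tabular homology output, and TSV matrices/edge lists. A
seeded fixture generator (`metnetweave.fixtures`) produces complete
synthetic studies with known ground truth, so the whole pipeline is testable
offline.

## Worked example

```python
from metnetweave import fixtures
from metnetweave.kegg_ingest import (parse_compound_dictionary, parse_ec_reactions,
                                     build_ec_metabolite_map)
from metnetweave.gen_builder import filter_common_metabolites, build_enzyme_network
from metnetweave.organism_mapping import (parse_homology_hits, assign_ec_to_genes,
                                          project_gene_network)
from metnetweave.expression_similarity import (collapse_probes, intersect_datasets,
                                               build_similarity_matrix)
from metnetweave.woen_builder import weight_network
from metnetweave.topology import summary_table

bundle = fixtures.generate_bundle(seed=1)          # synthetic study, known truth

mdict = parse_compound_dictionary(bundle.compound_text)
ecmap = build_ec_metabolite_map(parse_ec_reactions(bundle.enzyme_text), mdict)
filtered, removed = filter_common_metabolites(ecmap, n=3)
gen = build_enzyme_network(filtered)

gmap = assign_ec_to_genes(parse_homology_hits(bundle.hits_text), threshold=1e-5)
oen = project_gene_network(gmap, gen)

collapsed = [collapse_probes(t, bundle.probe_map) for t in bundle.probe_tables]
gesm = build_similarity_matrix(intersect_datasets(collapsed), bins="auto")
woen = weight_network(oen, gesm)

print("currency metabolites removed:", removed)
print(summary_table({"GEN": gen, "OEN": oen, "WOEN": woen}).round(3))
```

Output:

```
currency metabolites removed: ['C00001', 'C00002', 'C00003']
                                 GEN     OEN    WOEN
variable
n_nodes                       12.000  16.000  14.000
n_edges                       11.000  50.000  39.000
clustering_coefficient         0.286   0.611   0.605
clustering_coefficient_local   0.333   0.758   0.759
average_path_length            2.111   1.700   1.648
excluded_pairs                30.000   0.000   0.000
centralization                0.236    0.362   0.487
```

Reading the table: homology fans each of the 12 enzymatic activities out to
several genes, so the OEN has more nodes and far more edges than the GEN and
a shorter average path (1.70 vs 2.11) — the same qualitative transformation
seen on real organisms. Weighting then drops the two genes that lack
expression data (16 → 14 nodes) while leaving the surviving topology almost
unchanged; every retained edge carries its mutual-information weight in bits.

The same pipeline is available from the shell
(`metnetweave ingest | gen | oen | gesm | woen | topo | fixtures`); see
`metnetweave --help`.

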