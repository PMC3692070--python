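# metanet

A headless metagraph engine for building, filtering and analyzing
disease–gene–drug–therapy networks.

Translational network analysis asks questions that live across data layers:
which diseases share a genetic origin, which drugs might be repurposed
because their targets are disease-associated, which therapies correlate
through the targets of their drugs. `metanet` integrates the two kinds of
knowledge involved — hierarchical classifications (ICD-10-style disease
taxonomies, ATC-style therapy/drug taxonomies, GO-style DAGs) and adjacency
relations (disease–gene, therapy–drug, drug–target, gene–gene) — in a single
*metagraph*: a typed graph whose disease/therapy nodes are **metanodes**
embedding the genes/drugs annotated under their classification branch, with
collapse/expand state and provenance-tagged edges.

From one meta-network the engine derives the full family of 11 network
types: disease–disease and therapy–therapy correlation maps (edges weighted
by shared components |A∩B| or by cross-member association records),
disease–therapy, bipartite disease–gene and therapy–drug networks,
co-disease-gene and co-therapy-drug projections (two components linked when
they share a containing metanode), and the three- and four-layer joins
disease–gene–drug, therapy–drug–gene, disease–gene–drug–therapy.

On top of the graph model it provides hierarchy navigation (branch counts,
all paths to the root, term search), annotation-based and provenance-based
filtering, subset-restricted degree distributions, and hypergeometric
enrichment: a query gene set is scored against each term by the exact upper
tail

P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(K,i) C(N−K, n−i) / C(N, n)

with Benjamini–Hochberg adjustment, predicting the diseases/functions
associated with a gene set or the therapies associated with a drug set.

It is a library for people who script their analyses: systems-biology and
network-pharmacology researchers who want these constructions reproducible,
testable and headless (no GUI, no server). Networks read and write
tab-separated edge lists and a GML dialect that round-trips metanode
structure losslessly.

## Worked example

The bundled worked example (`metanet.fix1()`) is a four-term disease tree —
root `R`, children `D1` (cardiovascular), `D2` (neoplasms), `D1` having child
`D1a` (hypertension) — annotated with genes `D1a→{g1,g2}`, `D1→{g3}`,
`D2→{g2,g4}`, a two-term therapy tree `T1→{d1,d2}`, `T2→{d2}`, and a
drug–target table `d1→g1, d1→g2, d2→g4`.

```python
import metanet as mn

b = mn.fix1()
net = mn.derive_network(
    b.disease_hierarchy, b.therapy_hierarchy,
    b.disease_annotations, b.therapy_annotations,
    b.tables, ["D1", "D2"], ["T1", "T2"], "disease_therapy",
)
for e in net.edges.values():
    print(e.u, e.v, e.weight)
```

prints

```
D1 T1 2.0
D2 T1 2.0
D2 T2 1.0
```

— the disease–therapy network: `T1`'s drugs hit `D1`'s genes through two
drug–target records (`d1→g1`, `d1→g2`), and so on. Enriching the query
`{g1, g2}` against the disease tree
(`mn.enrich_terms({"g1","g2"}, b.disease_hierarchy, b.disease_annotations)`)
ranks `D1a` first with p = C(2,2)·C(2,0)/C(4,2) = 1/6 ≈ 0.1667: both query
genes fall in its 2-gene branch out of a 4-gene background. The
repositioning workflow for `D1`
(`mn.repositioning_candidates(...)`) returns `{'d1'}`: `d1` targets two
genes under the `D1` branch, while `d2` targets only `g4`, which is not.

The `examples/` directory holds one narrative script per capability —
hierarchy navigation, the 11 network types, enrichment, repositioning, and
synthetic bundle generation — each printing the numbers it computes and what
they mean.

## Acceptance script

`scripts/acceptance.py` exercises the engine end to end from a single seed:
it generates a synthetic annotated world, derives all 11 network types,
round-trips the meta-network through GML, runs planted-term enrichment and
the repositioning workflow, and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
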