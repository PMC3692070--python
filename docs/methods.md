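# Methods

## The metagraph model

`metanet` represents heterogeneous translational networks over four node
kinds — genes, drugs, diseases, therapies — in a single *metagraph*: an
undirected typed graph that admits *metanodes*, nodes containing other nodes.
A disease or therapy classification term becomes a metanode whose members are
the components (genes or drugs) annotated under its branch; membership may be
nested (a term embedding its sub-terms) and may overlap (one gene annotated
under two diseases), but never contains a metanode transitively within itself
— acyclicity is asserted after every mutation.

Edges carry a kind (`interaction`, `drug_target`, `disease_gene`,
`therapy_drug`, `shared_component`, `co_membership`), an optional non-negative
weight, and a set of *method tags* recording provenance (data source or
experiment type). At most one edge exists per (endpoint pair, kind); merging
the same pair from two sources unions the tags, which is what makes
method-based edge filtering additive.

### Collapse/expand semantics

The graph always stores the fully expanded edge set; the visible graph is a
derived *flat view*. A member of a collapsed metanode is hidden and its
external edges are summarized by a meta-edge between the metanode and the
external endpoint, with weight equal to the number of member edges summarized
and method tags unioned. Because collapse only changes view state, collapse
followed by expand is an identity by construction rather than by bookkeeping.
When overlapping metanodes are collapsed simultaneously, a hidden node's
visible representative is the collapsed container with the smallest id — an
arbitrary but deterministic tie-break.

### Metanode creation (drag & drop)

Four modes along two axes: `existing_*` modes intersect the term's branch
components with nodes already in the graph (the annotation-based node filter:
an empty result still creates the metanode, with a warning), while `all_*`
modes create missing component nodes; `*_with_subterms` modes nest one
metanode per child term holding at least one member (deeper recursion is
opt-in via `recursive=True`), with each component placed in its deepest
containing term only, so nothing is duplicated within one metanode tree.
Non-subterm modes flatten the branch into one member set.

GO-style (`function`) hierarchies are supported; since the node-kind
vocabulary is fixed at four, a function-term metanode takes the kind of its
components (a module of genes) rather than introducing a fifth kind.

## Hierarchies and annotation

Hierarchies are rooted DAGs parsed from a canonical 3-column TSV
(`term_id<TAB>parent_id<TAB>name`, empty parent for roots, repeated lines
merging parents); trees are the single-parent special case and multiple roots
are allowed (parallel classifications). Identifier matching is
case-insensitive with first-seen case preserved for display — but folding is
scoped per component kind, so a disease term `D1` never captures a drug named
`d1`.

Branch ("cumulative") counts are distinct-component unions over a term and
its descendants, which forces the invariant that the root count equals the
number of distinct annotated components and that counts are monotone up the
hierarchy. Path reporting enumerates every distinct parent-walk to a root,
sorted lexicographically. Term search matches a case-insensitive substring of
the name or a prefix of the id (so a query like `d1` finds both `D1` and
`D1a`, the way id searches behave in a hierarchy browser).

## Network transformations

All 11 network types derive from the meta-network:

- **Bipartite transform** — a metanode becomes a regular term node with one
  `disease_gene`/`therapy_drug` edge per former component member. Nested
  metanodes transform recursively; a component links to its innermost
  containing term only and no term–term edges are emitted, keeping the graph
  bipartite (term–term structure remains recoverable from the hierarchy).
- **Co-metanode transform** — metanodes are removed and every unordered pair
  of flattened members gains a `co_membership` edge weighted by the number of
  metanodes sharing the pair.
- **Shared-component edges** — metanode pairs weighted by flattened member
  intersection size (raw count by default; Jaccard normalization is an
  optional weight mode).
- **Interaction-based edges** — metanode pairs weighted by the number of
  association records (gene–gene or drug–target) linking a member of one to a
  member of the other. Records, not distinct drugs, are counted; with
  multi-target drugs the two conventions differ and the record count is the
  finer-grained one.

The disease–therapy network uses the drug–target record count between a
therapy's drugs and a disease's genes. The three-and four-layer joins
(`disease_gene_drug`, `therapy_drug_gene`, `disease_gene_drug_therapy`) query
the drug–target table from the genes and/or drugs present after the bipartite
step, creating the missing partner nodes. Node and edge output ordering is
sorted by id everywhere, so serialization is byte-identical across runs.

## Enrichment

For a query set against a hierarchy: background defaults to every component
annotated anywhere in the annotation set (the same universe the branch counts
display); query components outside the background are dropped and `n` counts
only what is retained, keeping the urn model coherent. Each term with at
least one background component in its branch is scored by the exact
upper-tail hypergeometric probability

P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(K,i) C(N−K, n−i) / C(N, n),

computed as a single integer-rational sum (`math.comb`), which is exact to
float rounding — the test suite checks it against exhaustive subset
enumeration for all N ≤ 12 and against `scipy.stats.hypergeom.sf`
independently. Adjustment is Benjamini–Hochberg by default (standard for term
enrichment; Bonferroni available), delegated to
`statsmodels.stats.multitest` and cross-checked against the direct step-up
formula in the tests. `p_adj` is computed across all K ≥ 1 terms so the
correction does not depend on whether k = 0 terms are displayed; ranking ties
break by term id.

Node annotation attaches the terms that annotate a component *directly* (the
most detailed knowledge level); `cumulative=True` attaches every branch
containing it, and ancestors are always recoverable through the path report.

## Filtering and statistics

Edge filters: any-match on method tags (an edge with one retained tag
survives, matching additive multi-source loading) and a weight threshold in
which unweighted edges count as weight 1 (the usual unweighted-graph
convention). Node filters: branch membership for a term, and the complement —
components with no annotation anywhere. Degree distributions are computed on
the flat view (collapsed metanodes contribute their meta-edges) and may be
restricted to one node kind; a restricted node still counts all incident
edges, since a drug's degree in a drug–target network *is* its number of gene
neighbors.

The repositioning workflow composes these primitives: filter the drug–target
network by a disease term, then collect the drugs adjacent to the surviving
genes. On any input it equals the brute-force relational
disease→gene→drug join restricted to drugs present in the network.

## Serialization

GML (via networkx, written as a multigraph so two edge kinds between one pair
survive) carries node kinds, metanode membership/state/origin and edge
kind/weight/method tags, and round-trips metagraphs losslessly; unknown node
attributes read into the property map. The edge-list dialect
(`source<TAB>target<TAB>method<TAB>weight`, one line per method tag) is the
lossy interchange format by design: metanode structure is flattened with a
warning, node kinds default to gene unless a sidecar kinds table is given,
and isolated nodes are not representable.

## The synthetic world

The generator emulates the shape of classification-plus-association data: a
complete b-ary disease tree truncated breadth-first to `n_terms`
(default depth 3, branching 3 → 40 terms, 27 leaves), leaf-annotated with
genes at `annotation_density` (default 0.08 over 200 genes, so a leaf branch
holds ~16 genes against a ~180-gene annotated background — a ≥10× background
in the typical draw, the regime the planted-recovery property conditions on);
a half-size therapy tree annotated with drugs the same way; Bernoulli
drug–target (density 0.03) and gene–gene (0.01) tables; and a query set
(size 12) drawing `planted_fraction` of its members from one planted term's
branch. Everything is driven by independent `numpy` sub-streams spawned from
one seed, so equal seeds give byte-identical bundles and adding an artifact
never perturbs the others.

What the generator does **not** emulate: realistic ICD-10/ATC code shapes,
degree-skewed (scale-free) drug–target topology, correlated annotations
between related terms, or biologically plausible associations. A green
planted-recovery test therefore establishes that the enrichment machinery
recovers a strong known signal in a favorable regime — not performance on
real curated databases. The hand-written worked-example bundle (`fix1()`) is
fixed code, not generated, so documented numbers never drift.

## Known limitations

- The flat view recomputes representatives globally; fine for the intended
  desk-scale graphs (10³–10⁴ nodes), not tuned for millions of edges.
- Hierarchy cycles are rejected, not repaired; obsolete/unplaced terms must
  be resolved before loading (every annotated term must exist).
- Statistical significance of disease–disease overlap weights (e.g. a
  permutation null) is out of scope; the weights are descriptive.
- Edge-list round trips preserve only what the dialect can express.
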