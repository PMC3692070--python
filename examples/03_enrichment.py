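"""Predict the diseases associated with a gene set by hypergeometric enrichment.

The query {g1, g2} is tested against every disease term's branch annotation.
For each term the table reports k (query genes under the branch), K (branch
genes in the background), n (query size), N (background size), the exact
upper-tail probability and its Benjamini-Hochberg adjustment.  The deepest
term containing both query genes (D1a) ranks first.
"""

import metanet as mn

b = mn.fix1()
results = mn.enrich_terms({"g1", "g2"}, b.disease_hierarchy, b.disease_annotations)

print(f"{'term':5s} {'name':26s} {'k':>2} {'K':>2} {'n':>2} {'N':>2} "
      f"{'p_raw':>8} {'p_adj':>8}")
for r in results:
    print(f"{r.term_id:5s} {r.name:26s} {r.k:>2} {r.K:>2} {r.n:>2} {r.N:>2} "
          f"{r.p_raw:8.4f} {r.p_adj:8.4f}")
print()
print("D1a: both query genes among its 2 branch genes -> p = 1/6 = C(2,2)/C(4,2).")
print("The root contains everything (K = N), so its p is 1 by construction.")
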