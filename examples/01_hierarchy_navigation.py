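"""Navigate a disease hierarchy: branch counts, root paths, term search.

Builds the small worked-example bundle (a four-term disease tree annotated
with four genes) and prints what a hierarchy explorer would show next to each
tree node: the number of distinct genes annotated under the branch.
"""

import metanet as mn

bundle = mn.fix1()
h, ann = bundle.disease_hierarchy, bundle.disease_annotations

print("Branch gene counts (distinct genes under each term):")
counts = mn.cumulative_counts(h, ann)
for term_id in sorted(h.terms):
    print(f"  {term_id:4s} {h.terms[term_id].name:28s} {counts[term_id]}")
print("The root count (4) is the number of distinct annotated genes;")
print("g2 sits under two branches but is counted once.\n")

print("All paths from 'D1a' to the root:")
for path in mn.paths_to_root(h, "D1a"):
    print("  " + " -> ".join(path))
print("A single-parent tree yields exactly one path per term.\n")

print("Search 'd1' (id prefix or name substring, case-insensitive):")
print("  hits:", mn.search_terms(h, "d1"))
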