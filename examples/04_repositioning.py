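"""Drug-repositioning shortlist: drugs whose targets are disease-associated.

Builds a drug-target network, filters it down to the genes annotated under
one disease branch (the annotation-based node filter), and collects the
drugs adjacent to the surviving genes — the candidates that might be
repurposed against that disease.
"""

import metanet as mn
from metanet.metagraph import MetaGraph, Node

b = mn.fix1()

# the drug-target network: every drug and gene in the association table
g = MetaGraph()
for drug, gene, method in sorted(b.tables["drug_target"].records):
    for nid, kind in ((drug, "drug"), (gene, "gene")):
        if nid not in g.nodes:
            g.add_node(Node(nid, kind))
    g.add_edge(drug, gene, edge_kind="drug_target", methods={method})

term = "D1"
marked = mn.filter_by_term(g, b.disease_hierarchy, b.disease_annotations, term)
print(f"Genes in the network annotated under disease branch {term}: {sorted(marked)}")

candidates = mn.repositioning_candidates(
    g, b.disease_hierarchy, b.disease_annotations, term, b.tables["drug_target"]
)
print(f"Repositioning candidates for {term}: {sorted(candidates)}")
print("d1 targets g1 and g2 (both under D1); d2 only targets g4, so it is out.")

hist = mn.degree_distribution(g, kind="drug")
print(f"Drug target-count histogram (degree -> #drugs): {hist.counts}")
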