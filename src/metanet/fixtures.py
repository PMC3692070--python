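"""Deterministic synthetic bundles: hierarchies, annotations, association
tables and queries with known planted structure.

The generator stands in for the real classification and association sources
(ICD-10/ATC dumps, curated disease-gene and drug-target tables): it emits a
disease hierarchy annotated with genes, a therapy hierarchy annotated with
drugs, gene-gene and drug-target association tables, and a query gene set
optionally enriched for one planted term.  Everything derives from a single
integer seed through independent sub-streams, so regenerating one artifact
never perturbs the others and equal seeds give byte-identical bundles.

``fix1()`` returns the small hand-written worked-example bundle used across
the documentation; it is fixed by hand so the documented numbers never drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .associations import AssociationTable, components_of_term, write_association_table
from .hierarchy import (
    AnnotationSet,
    Hierarchy,
    Term,
    write_annotations,
    write_hierarchy,
)

__all__ = ["FixtureError", "FixtureSpec", "Bundle", "generate_fixture", "fix1", "write_bundle"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and densities of a synthetic bundle.

    Defaults give a 3-level, 3-way disease tree (40 terms, 27 leaves) over
    200 genes at 8% leaf-annotation density, so a planted leaf branch
    (~16 genes) sits against a >=10x annotated background — the regime the
    planted-enrichment recovery property is stated for.
    """

    seed: int = 0
    n_terms: int = 40
    depth: int = 3
    branching: int = 3
    n_genes: int = 200
    n_drugs: int = 60
    annotation_density: float = 0.08
    planted_term: str | None = None
    planted_fraction: float = 0.8
    drug_target_density: float = 0.03
    gene_gene_density: float = 0.01
    query_size: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise FixtureError("planted_fraction must be in [0, 1]")
        max_terms = sum(self.branching**d for d in range(self.depth + 1))
        if self.n_terms > max_terms:
            raise FixtureError(
                f"cannot fit {self.n_terms} terms in a depth-{self.depth}, "
                f"branching-{self.branching} tree (max {max_terms})"
            )


@dataclass
class Bundle:
    """A generated world: two annotated hierarchies plus association layers."""

    disease_hierarchy: Hierarchy
    therapy_hierarchy: Hierarchy
    disease_annotations: AnnotationSet
    therapy_annotations: AnnotationSet
    tables: dict[str, AssociationTable]
    query: frozenset[str]
    extra_genes: frozenset[str] = field(default_factory=frozenset)


def _tree(prefix: str, n_terms: int, depth: int, branching: int, kind: str) -> Hierarchy:
    """Breadth-first complete tree truncated to n_terms, deterministic ids."""
    terms: dict[str, Term] = {}
    root = f"{prefix}0000"
    terms[root] = Term(root, f"{kind} root", frozenset())
    frontier = [root]
    counter = 1
    level = 0
    while counter < n_terms and level < depth:
        next_frontier = []
        for parent in frontier:
            for _ in range(branching):
                if counter >= n_terms:
                    break
                tid = f"{prefix}{counter:04d}"
                terms[tid] = Term(tid, f"{kind} term {counter}", frozenset({parent}))
                next_frontier.append(tid)
                counter += 1
        frontier = next_frontier
        level += 1
    return Hierarchy(terms, kind=kind)


def _leaves(h: Hierarchy) -> list[str]:
    return sorted(t for t in h.terms if not h.children(t))


def _annotate(
    h: Hierarchy, pool: list[str], density: float, kind: str, rng: np.random.Generator
) -> AnnotationSet:
    direct: dict[str, frozenset[str]] = {}
    for leaf in _leaves(h):
        mask = rng.random(len(pool)) < density
        members = frozenset(c for c, hit in zip(pool, mask) if hit)
        if members:
            direct[leaf] = members
    return AnnotationSet(direct, component_kind=kind, source="synthetic")


def _sample_pairs(
    lefts: list[str],
    rights: list[str],
    density: float,
    kind: str,
    method: str,
    rng: np.random.Generator,
    symmetric: bool = False,
) -> AssociationTable:
    table = AssociationTable(kind)
    for i, left in enumerate(lefts):
        row = rng.random(len(rights))
        for j, right in enumerate(rights):
            if symmetric and j <= i:
                continue
            if left != right and row[j] < density:
                table.add(left, right, method)
    return table


def generate_fixture(spec: FixtureSpec) -> Bundle:
    """Generate the full synthetic bundle for a :class:`FixtureSpec`."""
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_ann_d, rng_ann_t, rng_dt, rng_gg, rng_query = (
        np.random.default_rng(s) for s in streams
    )
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    drugs = [f"d{i:04d}" for i in range(spec.n_drugs)]
    h_d = _tree("DIS:", spec.n_terms, spec.depth, spec.branching, "disease")
    h_t = _tree("THR:", max(spec.n_terms // 2, 2), spec.depth, spec.branching, "therapy")
    a_d = _annotate(h_d, genes, spec.annotation_density, "gene", rng_ann_d)
    a_t = _annotate(h_t, drugs, spec.annotation_density, "drug", rng_ann_t)
    tables = {
        "drug_target": _sample_pairs(
            drugs, genes, spec.drug_target_density, "drug_target", "synthetic", rng_dt
        ),
        "gene_gene": _sample_pairs(
            genes, genes, spec.gene_gene_density, "gene_gene", "synthetic", rng_gg,
            symmetric=True,
        ),
    }
    query = _draw_query(spec, h_d, a_d, rng_query)
    return Bundle(h_d, h_t, a_d, a_t, tables, query)


def _draw_query(
    spec: FixtureSpec, h_d: Hierarchy, a_d: AnnotationSet, rng: np.random.Generator
) -> frozenset[str]:
    background = sorted(a_d.all_components())
    if not background:
        return frozenset()
    size = min(spec.query_size, len(background))
    if spec.planted_term is None:
        return frozenset(rng.choice(background, size=size, replace=False))
    planted_pool = sorted(components_of_term(h_d, a_d, spec.planted_term, True))
    if not planted_pool:
        raise FixtureError(
            f"planted term {spec.planted_term!r} has no annotated components"
        )
    n_planted = min(round(size * spec.planted_fraction), len(planted_pool))
    picked = set(rng.choice(planted_pool, size=n_planted, replace=False))
    rest_pool = [c for c in background if c not in picked]
    n_rest = min(size - len(picked), len(rest_pool))
    if n_rest > 0:
        picked |= set(rng.choice(rest_pool, size=n_rest, replace=False))
    return frozenset(picked)


def fix1() -> Bundle:
    """The hand-written worked-example bundle.

    Disease tree: root R with children D1, D2; D1 has child D1a.  Direct
    annotations D1a->{g1,g2}, D1->{g3}, D2->{g2,g4}.  Therapy tree: root TR
    with children T1->{d1,d2}, T2->{d2}.  Drug-target: d1->g1, d1->g2,
    d2->g4; gene-gene: g1-g2.  Gene g5 exists but is never annotated.
    """
    h_d = Hierarchy(
        {
            "R": Term("R", "diseases", frozenset()),
            "D1": Term("D1", "cardiovascular disorders", frozenset({"R"})),
            "D2": Term("D2", "neoplasms", frozenset({"R"})),
            "D1a": Term("D1a", "hypertension", frozenset({"D1"})),
        },
        kind="disease",
    )
    h_t = Hierarchy(
        {
            "TR": Term("TR", "therapies", frozenset()),
            "T1": Term("T1", "beta blocking agents", frozenset({"TR"})),
            "T2": Term("T2", "ace inhibitors", frozenset({"TR"})),
        },
        kind="therapy",
    )
    a_d = AnnotationSet(
        {
            "D1a": frozenset({"g1", "g2"}),
            "D1": frozenset({"g3"}),
            "D2": frozenset({"g2", "g4"}),
        },
        component_kind="gene",
        source="fix1",
    )
    a_t = AnnotationSet(
        {"T1": frozenset({"d1", "d2"}), "T2": frozenset({"d2"})},
        component_kind="drug",
        source="fix1",
    )
    drug_target = AssociationTable("drug_target")
    drug_target.add("d1", "g1", "M1")
    drug_target.add("d1", "g2", "M1")
    drug_target.add("d2", "g4", "M2")
    gene_gene = AssociationTable("gene_gene")
    gene_gene.add("g1", "g2", "Y2H")
    return Bundle(
        h_d,
        h_t,
        a_d,
        a_t,
        {"drug_target": drug_target, "gene_gene": gene_gene},
        query=frozenset({"g1", "g2"}),
        extra_genes=frozenset({"g5"}),
    )


def write_bundle(bundle: Bundle, directory: str | Path) -> list[Path]:
    """Write every bundle artifact as TSV files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    artifacts = {
        "disease_hierarchy.tsv": write_hierarchy(bundle.disease_hierarchy),
        "therapy_hierarchy.tsv": write_hierarchy(bundle.therapy_hierarchy),
        "disease_annotations.tsv": write_annotations(bundle.disease_annotations),
        "therapy_annotations.tsv": write_annotations(bundle.therapy_annotations),
        "query.txt": "\n".join(sorted(bundle.query)) + "\n",
    }
    for kind, table in sorted(bundle.tables.items()):
        artifacts[f"{kind}.tsv"] = write_association_table(table)
    for name, payload in artifacts.items():
        path = directory / name
        path.write_text(payload)
        written.append(path)
    return written
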