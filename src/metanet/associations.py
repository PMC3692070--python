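"""Relational association layers: disease-gene, therapy-drug, drug-target, gene-gene.

Each table is a set of ``(left_id, right_id, method_tag)`` records.  The left
and right roles are fixed by the table kind (drug_target: left=drug,
right=gene; disease_gene: left=disease term, right=gene; therapy_drug:
left=therapy term, right=drug).  Gene-gene interaction is undirected; the
other kinds carry directed role semantics.  The method tag records provenance
(data source or experiment type) and scopes deduplication: the same pair
under two methods is two records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .hierarchy import AnnotationSet, Hierarchy, descendants

__all__ = [
    "ASSOCIATION_KINDS",
    "AssociationError",
    "AssociationTable",
    "load_association_table",
    "write_association_table",
    "components_of_term",
    "neighbors",
]

ASSOCIATION_KINDS = ("disease_gene", "therapy_drug", "drug_target", "gene_gene")


class AssociationError(ValueError):
    pass


def _fold(identifier: str) -> str:
    return identifier.casefold()


@dataclass
class AssociationTable:
    kind: str
    records: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in ASSOCIATION_KINDS:
            raise AssociationError(f"unknown association kind {self.kind!r}")
        self.records = set(self.records)

    def add(self, left: str, right: str, method: str = "unspecified") -> None:
        self.records.add((left, right, method))

    def __len__(self) -> int:
        return len(self.records)

    def method_tags(self) -> set[str]:
        return {m for _, _, m in self.records}


def load_association_table(stream, kind: str) -> AssociationTable:
    """Load a ``left_id<TAB>right_id[<TAB>method_tag]`` TSV.

    The method tag defaults to ``unspecified``; exact duplicate records
    collapse, while the same pair under two method tags yields two records.
    """
    table = AssociationTable(kind)
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    canonical: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if _fold(fields[0]) in ("left_id", "source"):
            continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise AssociationError(
                f"line {lineno}: expected left_id<TAB>right_id[<TAB>method_tag]"
            )
        left = canonical.setdefault(_fold(fields[0].strip()), fields[0].strip())
        right = canonical.setdefault(_fold(fields[1].strip()), fields[1].strip())
        method = fields[2].strip() if len(fields) > 2 and fields[2].strip() else "unspecified"
        table.add(left, right, method)
    return table


def write_association_table(t: AssociationTable) -> str:
    lines = [f"# kind: {t.kind}", "left_id\tright_id\tmethod_tag"]
    for left, right, method in sorted(t.records):
        lines.append(f"{left}\t{right}\t{method}")
    return "\n".join(lines) + "\n"


def components_of_term(
    h: Hierarchy,
    a: AnnotationSet,
    term_id: str,
    include_descendants: bool = True,
) -> frozenset[str]:
    """Components annotated to a term, optionally unioned over its branch."""
    canonical = h.resolve(term_id)
    out = set(a.direct_components(h, canonical))
    if include_descendants:
        for sub in descendants(h, canonical):
            out.update(a.direct_components(h, sub))
    return frozenset(out)


def neighbors(
    table: AssociationTable, ids: set[str], side: str = "left"
) -> set[tuple[str, str]]:
    """Partners of any id in *ids* on the stated side, with their method tags.

    ``side="left"`` means the query ids play the left role and the returned
    partners come from the right column (and vice versa).  For gene_gene
    tables the relation is symmetric and both columns are searched.
    """
    if side not in ("left", "right"):
        raise AssociationError(f"side must be left or right, got {side!r}")
    folded = {_fold(i) for i in ids}
    out: set[tuple[str, str]] = set()
    for left, right, method in table.records:
        if table.kind == "gene_gene":
            if _fold(left) in folded:
                out.add((right, method))
            if _fold(right) in folded:
                out.add((left, method))
        elif side == "left" and _fold(left) in folded:
            out.add((right, method))
        elif side == "right" and _fold(right) in folded:
            out.add((left, method))
    return out
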