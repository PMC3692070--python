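"""Term hierarchies (ICD-10/ATC-style trees, GO-style DAGs) with component annotation.

A :class:`Hierarchy` is a rooted directed acyclic graph of terms.  Trees
(ICD-10, ATC) are the single-parent special case; GO-style terms may carry
several parents, and several roots may coexist (e.g. one per source
classification).  An :class:`AnnotationSet` maps terms to the genes or drugs
directly annotated under them; branch ("cumulative") counts union the
annotations of a term and all of its descendants, counting each component
once.

Identifier matching is case-insensitive throughout, with the first-seen
spelling preserved for display.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "HierarchyError",
    "Term",
    "Hierarchy",
    "AnnotationSet",
    "parse_hierarchy",
    "write_hierarchy",
    "parse_annotations",
    "write_annotations",
    "descendants",
    "cumulative_counts",
    "cumulative_components",
    "paths_to_root",
    "search_terms",
]

HIERARCHY_KINDS = ("disease", "therapy", "function")


class HierarchyError(ValueError):
    """Raised for malformed hierarchy files or queries on unknown terms."""


def _fold(identifier: str) -> str:
    return identifier.casefold()


@dataclass(frozen=True)
class Term:
    """A single classification term."""

    term_id: str
    name: str
    parent_ids: frozenset[str]

    @property
    def is_root(self) -> bool:
        return not self.parent_ids


class Hierarchy:
    """An indexed, acyclic term hierarchy.

    Parameters
    ----------
    terms
        Mapping from term id to :class:`Term`.  Parent references must be
        resolvable within the mapping and acyclic.
    kind
        One of ``disease``, ``therapy`` or ``function``.
    """

    def __init__(self, terms: Mapping[str, Term], kind: str = "disease"):
        if kind not in HIERARCHY_KINDS:
            raise HierarchyError(f"unknown hierarchy kind {kind!r}")
        self.kind = kind
        self.terms: dict[str, Term] = dict(terms)
        self._index: dict[str, str] = {}
        for tid in self.terms:
            folded = _fold(tid)
            if folded in self._index:
                raise HierarchyError(f"duplicate term id {tid!r} (case-insensitive)")
            self._index[folded] = tid
        self._children: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for tid, term in self.terms.items():
            for pid in term.parent_ids:
                if _fold(pid) not in self._index:
                    raise HierarchyError(
                        f"term {tid!r} references undeclared parent {pid!r}"
                    )
                self._children[self.resolve(pid)].add(tid)
        self._assert_acyclic()

    # -- indexing ---------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Return the canonical spelling of *term_id*; raise if unknown."""
        try:
            return self._index[_fold(term_id)]
        except KeyError:
            raise HierarchyError(f"unknown term {term_id!r}") from None

    def __contains__(self, term_id: str) -> bool:
        return _fold(term_id) in self._index

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def roots(self) -> set[str]:
        return {tid for tid, t in self.terms.items() if t.is_root}

    def children(self, term_id: str) -> set[str]:
        return set(self._children[self.resolve(term_id)])

    def parents(self, term_id: str) -> set[str]:
        return {self.resolve(p) for p in self.terms[self.resolve(term_id)].parent_ids}

    def _assert_acyclic(self) -> None:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        for tid, kids in self._children.items():
            dg.add_edges_from((tid, k) for k in kids)
        try:
            cycle = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            return
        raise HierarchyError(f"hierarchy contains a cycle through term {cycle[0][0]!r}")


@dataclass
class AnnotationSet:
    """Direct term -> component annotations paired with a hierarchy.

    ``component_kind`` is ``gene`` or ``drug``; ``source`` is a free-form
    provenance tag.  Component sets may overlap across terms.
    """

    direct: dict[str, frozenset[str]]
    component_kind: str = "gene"
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if self.component_kind not in ("gene", "drug"):
            raise HierarchyError(
                f"component_kind must be gene or drug, got {self.component_kind!r}"
            )
        self.direct = {t: frozenset(cs) for t, cs in self.direct.items()}

    def validate(self, hierarchy: Hierarchy) -> None:
        for tid in self.direct:
            if tid not in hierarchy:
                raise HierarchyError(f"annotation references unknown term {tid!r}")

    def direct_components(self, hierarchy: Hierarchy, term_id: str) -> frozenset[str]:
        canonical = hierarchy.resolve(term_id)
        for tid, comps in self.direct.items():
            if _fold(tid) == _fold(canonical):
                return comps
        return frozenset()

    def all_components(self) -> frozenset[str]:
        out: set[str] = set()
        for comps in self.direct.values():
            out.update(comps)
        return frozenset(out)


# -- parsing / serialization ---------------------------------------------


def _iter_lines(stream) -> Iterable[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def parse_hierarchy(stream, kind: str = "disease") -> Hierarchy:
    """Parse a 3-column TSV (``term_id<TAB>parent_id<TAB>name``) hierarchy.

    An empty ``parent_id`` marks a root.  A term id may appear on several
    lines; their parents are merged (DAG support).  A header line whose first
    field is ``term_id`` is skipped, as are blank and ``#`` comment lines.
    """
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    order: list[str] = []
    seen: dict[str, str] = {}  # folded -> canonical
    pending: list[tuple[int, str, str]] = []  # lineno, term, parent
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if _fold(fields[0]) == "term_id":
            continue
        if len(fields) < 2:
            raise HierarchyError(
                f"line {lineno}: expected term_id<TAB>parent_id[<TAB>name]"
            )
        tid_raw, pid_raw = fields[0].strip(), fields[1].strip()
        name = fields[2].strip() if len(fields) > 2 else ""
        folded = _fold(tid_raw)
        tid = seen.setdefault(folded, tid_raw)
        if tid not in parents:
            parents[tid] = set()
            order.append(tid)
        if name and not names.get(tid):
            names[tid] = name
        if pid_raw:
            pending.append((lineno, tid, pid_raw))
    for lineno, tid, pid_raw in pending:
        pid = seen.get(_fold(pid_raw))
        if pid is None:
            raise HierarchyError(
                f"line {lineno}: parent {pid_raw!r} of {tid!r} is not declared"
            )
        if pid != tid:
            parents[tid].add(pid)
        else:
            raise HierarchyError(f"line {lineno}: term {tid!r} is its own parent")
    terms = {
        tid: Term(tid, names.get(tid, tid), frozenset(parents[tid])) for tid in order
    }
    return Hierarchy(terms, kind=kind)


def write_hierarchy(h: Hierarchy) -> str:
    """Serialize to the canonical 3-column TSV, terms sorted by id."""
    lines = ["term_id\tparent_id\tname"]
    for tid in sorted(h.terms):
        term = h.terms[tid]
        if term.is_root:
            lines.append(f"{tid}\t\t{term.name}")
        else:
            for pid in sorted(term.parent_ids):
                lines.append(f"{tid}\t{pid}\t{term.name}")
    return "\n".join(lines) + "\n"


def parse_annotations(
    stream, component_kind: str = "gene", hierarchy: Hierarchy | None = None
) -> AnnotationSet:
    """Parse ``term_id<TAB>component_id<TAB>source`` annotation TSV."""
    direct: dict[str, set[str]] = {}
    canonical_components: dict[str, str] = {}
    source_tags: set[str] = set()
    for lineno, line in _iter_lines(stream):
        fields = line.split("\t")
        if _fold(fields[0]) == "term_id":
            continue
        if len(fields) < 2:
            raise HierarchyError(
                f"line {lineno}: expected term_id<TAB>component_id[<TAB>source]"
            )
        tid, comp = fields[0].strip(), fields[1].strip()
        if len(fields) > 2 and fields[2].strip():
            source_tags.add(fields[2].strip())
        if hierarchy is not None:
            tid = hierarchy.resolve(tid)
        comp = canonical_components.setdefault(_fold(comp), comp)
        direct.setdefault(tid, set()).add(comp)
    source = ",".join(sorted(source_tags)) if source_tags else "unspecified"
    ann = AnnotationSet(
        {t: frozenset(c) for t, c in direct.items()},
        component_kind=component_kind,
        source=source,
    )
    if hierarchy is not None:
        ann.validate(hierarchy)
    return ann


def write_annotations(a: AnnotationSet) -> str:
    lines = ["term_id\tcomponent_id\tsource"]
    for tid in sorted(a.direct):
        for comp in sorted(a.direct[tid]):
            lines.append(f"{tid}\t{comp}\t{a.source}")
    return "\n".join(lines) + "\n"


# -- queries --------------------------------------------------------------


def descendants(h: Hierarchy, term_id: str) -> set[str]:
    """All terms reachable from *term_id* by child edges (excluding itself)."""
    start = h.resolve(term_id)
    out: set[str] = set()
    stack = [start]
    while stack:
        for kid in h.children(stack.pop()):
            if kid not in out:
                out.add(kid)
                stack.append(kid)
    return out


def cumulative_components(h: Hierarchy, a: AnnotationSet) -> dict[str, frozenset[str]]:
    """Branch component sets: per term, the union of direct annotations over
    the term and all of its descendants (each component counted once)."""
    a.validate(h)
    direct = {h.resolve(t): set(cs) for t, cs in a.direct.items()}
    memo: dict[str, frozenset[str]] = {}

    def cum(tid: str) -> frozenset[str]:
        if tid in memo:
            return memo[tid]
        out = set(direct.get(tid, ()))
        for kid in h.children(tid):
            out.update(cum(kid))
        memo[tid] = frozenset(out)
        return memo[tid]

    # iterative-friendly: hierarchies are shallow, recursion depth = depth
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(h.terms) + 100))
    try:
        return {tid: cum(tid) for tid in h.terms}
    finally:
        sys.setrecursionlimit(old)


def cumulative_counts(h: Hierarchy, a: AnnotationSet) -> dict[str, int]:
    """Per-term branch counts: distinct components annotated under the branch."""
    return {tid: len(cs) for tid, cs in cumulative_components(h, a).items()}


def paths_to_root(h: Hierarchy, term_id: str) -> list[list[str]]:
    """Enumerate every distinct parent-walk from *term_id* to a root.

    Paths are returned as term-id sequences starting at the query term and
    ending at a root, sorted lexicographically for determinism.
    """
    start = h.resolve(term_id)
    paths: list[list[str]] = []

    def walk(tid: str, acc: list[str]) -> None:
        parents = sorted(h.parents(tid))
        if not parents:
            paths.append(list(acc))
            return
        for pid in parents:
            acc.append(pid)
            walk(pid, acc)
            acc.pop()

    walk(start, [start])
    paths.sort()
    return paths


def search_terms(h: Hierarchy, query: str) -> list[str]:
    """Search by keyword or id: case-insensitive substring match on the term
    name, or prefix match on the term id.  Results sorted by term id."""
    if not query:
        raise HierarchyError("query must be nonempty")
    q = _fold(query)
    hits = [
        tid
        for tid, term in h.terms.items()
        if _fold(tid).startswith(q) or q in _fold(term.name)
    ]
    return sorted(hits)
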