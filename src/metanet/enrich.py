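"""Hypergeometric term enrichment and node annotation.

Given a query set of genes (or drugs) and a term hierarchy with component
annotation, each term is scored by the upper-tail hypergeometric probability
of drawing at least ``k`` of its ``K`` branch-annotated components in a
sample of ``n`` from a background of ``N`` — the classic urn model used to
predict the diseases/functions associated with a gene set, or the therapies
associated with a drug set.

The tail is computed with exact integer combinatorics (no cancellation);
multiplicity adjustment is Benjamini-Hochberg by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

from statsmodels.stats.multitest import multipletests

from .hierarchy import AnnotationSet, Hierarchy, cumulative_components
from .metagraph import MetaGraph, MetaGraphError

__all__ = [
    "EnrichmentError",
    "EnrichmentResult",
    "hypergeom_tail",
    "adjust_pvalues",
    "enrich_terms",
    "annotate_nodes",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and probabilities for one term.

    k: query components annotated under the term's branch;
    n: query size counted in the background;
    K: background components annotated under the branch;
    N: background size.
    """

    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts annotated components in a uniform draw of n items from a
    background of N containing K annotated ones.  Computed as a single
    integer-rational sum, so it is exact to float rounding.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(value, int) or value < 0:
            raise EnrichmentError(f"{name} must be a non-negative integer")
    if k > min(n, K) or K > N or n > N:
        raise EnrichmentError(
            f"invalid counts: need k <= min(n, K), K <= N, n <= N "
            f"(got k={k}, K={K}, n={n}, N={N})"
        )
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return numerator / comb(N, n)


def adjust_pvalues(ps: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment, positionally mapped back to the input.

    ``bh`` is Benjamini-Hochberg step-up, ``bonferroni`` multiplies by the
    number of tests (capped at 1), ``none`` is the identity.
    """
    if method not in ("bh", "bonferroni", "none"):
        raise EnrichmentError(f"unknown adjustment method {method!r}")
    ps = list(ps)
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise EnrichmentError(f"p-value {p!r} outside (0, 1]")
    if not ps or method == "none":
        return ps
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return list(multipletests(ps, method=sm_method)[1])


def enrich_terms(
    query: Iterable[str],
    h: Hierarchy,
    a: AnnotationSet,
    background: Iterable[str] | str = "all_annotated",
    method: str = "bh",
    include_unhit: bool = False,
) -> list[EnrichmentResult]:
    """Score every annotated term against a query component set.

    The background defaults to every component annotated anywhere in the
    hierarchy (matching the per-branch counts a navigator displays); query
    components outside the background are dropped.  Terms use cumulative
    (branch) annotation; terms with ``K == 0`` never appear, and terms the
    query misses (``k == 0``) appear only when ``include_unhit`` is set.
    Results are sorted by (p_raw, term_id); ``p_adj`` is adjusted across all
    K >= 1 terms so the correction does not depend on the display filter.
    """
    a.validate(h)
    cumulative = cumulative_components(h, a)
    if isinstance(background, str):
        if background != "all_annotated":
            raise EnrichmentError(f"unknown background spec {background!r}")
        bg = set(a.all_components())
    else:
        bg = set(background)
    bg_folded = {c.casefold(): c for c in bg}
    effective_query = {
        bg_folded[q.casefold()] for q in query if q.casefold() in bg_folded
    }
    if not effective_query:
        raise EnrichmentError("query is empty after intersecting with the background")
    N, n = len(bg), len(effective_query)
    query_folded = {c.casefold() for c in effective_query}

    rows: list[tuple[str, int, int, float]] = []
    for tid in sorted(h.terms):
        branch = {c.casefold() for c in cumulative[tid]} & set(bg_folded)
        K = len(branch)
        if K == 0:
            continue
        k = len(branch & query_folded)
        rows.append((tid, k, K, hypergeom_tail(k, K, n, N)))
    adjusted = adjust_pvalues([r[3] for r in rows], method=method)
    results = [
        EnrichmentResult(tid, h.terms[tid].name, k, K, n, N, p, p_adj)
        for (tid, k, K, p), p_adj in zip(rows, adjusted)
        if include_unhit or k > 0
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def annotate_nodes(
    g: MetaGraph,
    h: Hierarchy,
    a: AnnotationSet,
    add: bool = True,
    cumulative: bool = False,
    nodes: Iterable[str] | None = None,
) -> MetaGraph:
    """Add or remove term annotations on the matching component nodes.

    Gene annotations apply to gene nodes, drug (therapy/ATC) annotations to
    drug nodes.  By default a node gains the terms that annotate it
    *directly* (the most detailed knowledge); set ``cumulative=True`` to also
    attach every ancestor term whose branch contains the node.  The terms are
    stored in the node property ``"annotations"`` as a sorted
    comma-separated string.  Passing explicit ``nodes`` of the wrong kind is
    an error; by default all matching-kind nodes are processed.
    """
    a.validate(h)
    if nodes is None:
        targets = [nid for nid, node in g.nodes.items() if node.kind == a.component_kind]
    else:
        targets = []
        for nid in nodes:
            if nid not in g.nodes:
                raise MetaGraphError(f"unknown node {nid!r}")
            if g.nodes[nid].kind != a.component_kind:
                raise EnrichmentError(
                    f"annotation kind {a.component_kind!r} does not apply to "
                    f"{nid!r} of kind {g.nodes[nid].kind!r}"
                )
            targets.append(nid)
    term_sets = (
        cumulative_components(h, a)
        if cumulative
        else {h.resolve(t): cs for t, cs in a.direct.items()}
    )
    for nid in targets:
        folded = nid.casefold()
        hits = {
            tid
            for tid, comps in term_sets.items()
            if folded in {c.casefold() for c in comps}
        }
        node = g.nodes[nid]
        current = set(filter(None, node.properties.get("annotations", "").split(",")))
        current = (current | hits) if add else (current - hits)
        if current:
            node.properties["annotations"] = ",".join(sorted(current))
        else:
            node.properties.pop("annotations", None)
    return g
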