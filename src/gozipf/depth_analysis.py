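"""Ontology depth of frequently vs rarely used terms.

Frequently used GO terms tend to be generic — close to the root of
their sub-ontology — while rarely used terms are specific and deep.
Depth here is the length of the shortest is_a path from a term to its
sub-ontology root (root depth 0). The comparison contrasts the mean
depth of the top quartile of terms by usage frequency with that of the
bottom quartile, and a paired t-test across corpora tests whether the
shallow-frequent pattern is systematic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from gozipf.ontology_io import OntologyGraph


class UnknownTermError(KeyError):
    """The term is not present in the ontology."""


class ObsoleteTermError(ValueError):
    """The term is obsolete and excluded from depth analysis."""


class DegenerateInputError(ValueError):
    """The paired differences have zero variance; the t-test is undefined."""


@dataclass(frozen=True)
class DepthComparison:
    """Mean ontology depth of the most- vs least-used term quartiles."""

    corpus_label: str
    n_top: int
    mean_depth_top: float
    n_bottom: int
    mean_depth_bottom: float


def _namespace_depths(graph: OntologyGraph, namespace: str) -> dict[str, int]:
    """Shortest is_a distance to the namespace root for every term."""
    roots = graph.roots(namespace)
    if not roots:
        raise UnknownTermError(f"namespace {namespace} has no root")
    rev = graph.graph.reverse(copy=False)
    depths: dict[str, int] = {}
    for root in roots:
        for term, d in nx.single_source_shortest_path_length(rev, root).items():
            if graph.namespace.get(term) != namespace:
                continue
            if term not in depths or d < depths[term]:
                depths[term] = d
    return depths


def term_depth(graph: OntologyGraph, term: str) -> int:
    """Length of the shortest is_a path from ``term`` to its namespace root.

    Alternate ids are resolved first. The root itself has depth 0.

    Raises
    ------
    UnknownTermError
        If the term is absent from the graph or has no namespace.
    ObsoleteTermError
        If the term is obsolete.
    """
    term = graph.resolve(term)
    if term in graph.obsolete:
        raise ObsoleteTermError(f"term {term} is obsolete")
    if term not in graph.graph:
        raise UnknownTermError(f"term {term} not in ontology")
    ns = graph.namespace.get(term)
    if ns is None:
        raise UnknownTermError(f"term {term} has no namespace; depth undefined")
    depths = _namespace_depths(graph, ns)
    if term not in depths:
        raise UnknownTermError(f"term {term} is disconnected from its root")
    return depths[term]


def quartile_depth_comparison(
    table, graph: OntologyGraph, corpus_label: str = ""
) -> DepthComparison:
    """Mean depth of the top vs bottom frequency quartiles of distinct terms.

    Quartiles are taken over distinct terms (not annotation tokens),
    each holding floor(n/4) terms; the frequency table's deterministic
    rank order (ties by term id) resolves boundary ties.
    """
    n = len(table)
    if n < 4:
        raise ValueError(f"need at least 4 distinct terms, got {n}")
    q = n // 4
    terms = table.sort_values("rank")["term"].tolist()

    # one BFS per namespace involved, then dictionary lookups
    cache: dict[str, dict[str, int]] = {}

    def depth_of(term: str) -> int:
        t = graph.resolve(term)
        ns = graph.namespace.get(t)
        if t in graph.obsolete:
            raise ObsoleteTermError(f"term {t} is obsolete")
        if ns is None or t not in graph.graph:
            raise UnknownTermError(f"term {term} not resolvable in ontology")
        if ns not in cache:
            cache[ns] = _namespace_depths(graph, ns)
        return cache[ns][t]

    top = [depth_of(t) for t in terms[:q]]
    bottom = [depth_of(t) for t in terms[-q:]]
    return DepthComparison(
        corpus_label=corpus_label,
        n_top=q,
        mean_depth_top=float(np.mean(top)),
        n_bottom=q,
        mean_depth_bottom=float(np.mean(bottom)),
    )


def depth_significance(
    comparisons: list[DepthComparison], sides: str = "two"
) -> tuple[float, int, float]:
    """Paired t-test of top-quartile vs bottom-quartile mean depths.

    Pairs are the (mean_depth_top, mean_depth_bottom) values of each
    corpus. ``sides='one'`` tests the directional hypothesis that
    frequent terms are shallower (top < bottom).

    Returns (t, degrees of freedom, p).
    """
    if len(comparisons) < 2:
        raise ValueError("need at least 2 corpora for a paired t-test")
    top = np.array([c.mean_depth_top for c in comparisons])
    bottom = np.array([c.mean_depth_bottom for c in comparisons])
    diffs = top - bottom
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DegenerateInputError("paired differences have zero variance")
    alternative = "two-sided" if sides == "two" else "less"
    res = stats.ttest_rel(top, bottom, alternative=alternative)
    return float(res.statistic), len(comparisons) - 1, float(res.pvalue)
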