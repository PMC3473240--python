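"""Stratified annotation corpora and term-frequency tables.

A corpus is the multiset of GO term ids drawn from the annotation lines
of one sub-ontology (MF/BP/CC), optionally restricted to an
evidence-code class. Each surviving GAF line contributes one token, so
the same gene-term pair annotated under two evidence codes counts
twice — totals then match "number of annotations" bookkeeping. The
frequency table (term, frequency, rank) is the object whose tail the
power-law fitter consumes.

Evidence-code classes follow the curation split used for GOA corpora:
HC (high confidence) collects the manually/experimentally supported
codes, LC (low confidence) is electronic annotation only (IEA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from gozipf.ontology_io import ASPECT_TO_NAMESPACE, AnnotationRecord, OntologyGraph


class EmptyCorpusError(ValueError):
    """No annotation survived filtering; frequency fitting is undefined."""


@dataclass(frozen=True)
class EvidenceClass:
    """A named set of GO evidence codes used to stratify a corpus.

    ``codes=None`` means the universal set (no evidence filtering).
    """

    name: str
    codes: frozenset[str] | None = None

    def __contains__(self, code: str) -> bool:
        return self.codes is None or code in self.codes


#: Experimentally / manually supported evidence codes.
HC = EvidenceClass(
    "HC", frozenset({"IDA", "IPI", "IMP", "TAS", "EXP", "IC", "IEP", "IGI"})
)
#: Electronic annotation only.
LC = EvidenceClass("LC", frozenset({"IEA"}))
#: No evidence filtering.
ALL = EvidenceClass("ALL", None)


def evidence_class(name: str, codes: Iterable[str] | None = None) -> EvidenceClass:
    """Return a built-in class by name, or a CUSTOM class from ``codes``."""
    builtin = {"ALL": ALL, "HC": HC, "LC": LC}
    if name.upper() in builtin:
        return builtin[name.upper()]
    if codes is None:
        raise ValueError(f"unknown evidence class {name!r} and no codes given")
    return EvidenceClass("CUSTOM", frozenset(c.upper() for c in codes))


@dataclass
class Corpus:
    """The multiset of GO term tokens for one (aspect, evidence class) stratum."""

    tokens: list[str]
    aspect: str
    evidence_class: EvidenceClass = ALL
    source_label: str = ""

    @property
    def total_annotations(self) -> int:
        return len(self.tokens)

    @property
    def distinct_terms(self) -> int:
        return len(set(self.tokens))


def build_corpus(
    records: list[AnnotationRecord],
    aspect: str,
    evidence_class: EvidenceClass = ALL,
    exclude_negated: bool = True,
    graph: OntologyGraph | None = None,
    dedupe: bool = False,
    source_label: str = "",
) -> Corpus:
    """Collect the GO-term tokens of one sub-ontology / evidence stratum.

    Parameters
    ----------
    aspect : str
        GAF aspect letter (``F``/``P``/``C``) or sub-ontology short name
        (``MF``/``BP``/``CC``).
    evidence_class : EvidenceClass
        Only records whose evidence code belongs to the class survive.
    exclude_negated : bool
        Drop NOT-qualified annotations (default): a statement that a
        gene product does *not* have a function is not a use of the
        term in the Zipfian sense.
    graph : OntologyGraph, optional
        When given, alternate GO ids are resolved to primary ids.
    dedupe : bool
        Keep at most one token per (gene product, term) pair instead of
        one per GAF line.

    Raises
    ------
    EmptyCorpusError
        If no record survives the filters.
    """
    ns = ASPECT_TO_NAMESPACE.get(aspect, aspect)
    if ns not in ASPECT_TO_NAMESPACE.values():
        raise ValueError(f"unknown aspect {aspect!r}")

    tokens: list[str] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if ASPECT_TO_NAMESPACE[rec.aspect] != ns:
            continue
        if rec.evidence_code not in evidence_class:
            continue
        if exclude_negated and rec.negated:
            continue
        term = graph.resolve(rec.go_id) if graph is not None else rec.go_id
        if dedupe:
            key = (rec.db_object_id, term)
            if key in seen:
                continue
            seen.add(key)
        tokens.append(term)
    if not tokens:
        raise EmptyCorpusError(
            f"no annotations for aspect={ns}, evidence={evidence_class.name}"
        )
    return Corpus(tokens=tokens, aspect=ns, evidence_class=evidence_class,
                  source_label=source_label)


def frequency_table(corpus: Corpus) -> pd.DataFrame:
    """Term frequencies ranked by descending count.

    Returns a DataFrame with columns ``term``, ``frequency``, ``rank``
    (rank 1 = most frequent). Frequency ties are broken by lexicographic
    term id so the ranking is deterministic.
    """
    if not corpus.tokens:
        raise EmptyCorpusError("cannot tabulate an empty corpus")
    counts = Counter(corpus.tokens)
    df = pd.DataFrame(sorted(counts.items()), columns=["term", "frequency"])
    df = df.sort_values(["frequency", "term"], ascending=[False, True],
                        kind="mergesort", ignore_index=True)
    df["rank"] = df.index + 1
    return df


def corpus_summary(corpora: list[Corpus]) -> pd.DataFrame:
    """One row per corpus: totals and distinct-term counts.

    Mirrors the usual per-species / per-sub-ontology summary of an
    annotation release (total number of annotations, number of distinct
    GO identifiers).
    """
    rows = [
        {
            "source": c.source_label,
            "aspect": c.aspect,
            "evidence_class": c.evidence_class.name,
            "total_annotations": c.total_annotations,
            "distinct_go_ids": c.distinct_terms,
        }
        for c in corpora
    ]
    return pd.DataFrame(
        rows,
        columns=["source", "aspect", "evidence_class",
                 "total_annotations", "distinct_go_ids"],
    )
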