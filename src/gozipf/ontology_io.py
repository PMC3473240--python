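"""Readers and writers for GAF 2.x annotation files and OBO 1.2 ontologies.

GAF (Gene Association File) is the tab-delimited exchange format for GO
annotations: one gene-product/term association per line, ``!``-prefixed
comment lines, 17 columns (1-based: column 4 qualifier, 5 GO id, 7
evidence code, 9 aspect letter F/P/C). OBO 1.2 is the flat-file ontology
format; only ``is_a`` edges are loaded here, since term depth is defined
along ``is_a`` paths.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: GAF aspect letter -> sub-ontology short name
ASPECT_TO_NAMESPACE = {"F": "MF", "P": "BP", "C": "CC"}
#: OBO namespace string -> sub-ontology short name
OBO_NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

GAF_HEADER = "!gaf-version: 2.0"
_GAF_NCOL = 17


class EmptyInputError(ValueError):
    """A stream yielded no parseable content."""


class OntologyStructureError(ValueError):
    """The ontology violates a structural requirement (e.g. cyclic is_a)."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF annotation line.

    Parameters
    ----------
    db : str
        Source database (GAF column 1).
    db_object_id : str
        Gene-product identifier (column 2).
    go_id : str
        GO term identifier, ``GO:`` followed by 7 digits (column 5).
    qualifier : tuple of str
        Qualifier tokens from column 4 (e.g. ``NOT``); empty if none.
    aspect : str
        Sub-ontology letter: ``F`` (molecular function), ``P``
        (biological process) or ``C`` (cellular component) (column 9).
    evidence_code : str
        Evidence code such as ``IDA`` or ``IEA`` (column 7).
    taxon : str
        Taxon field (column 13), optional.
    """

    db: str
    db_object_id: str
    go_id: str
    qualifier: tuple[str, ...] = ()
    aspect: str = "P"
    evidence_code: str = "IEA"
    taxon: str = ""

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.go_id):
            raise ValueError(f"not a GO identifier: {self.go_id!r}")
        if self.aspect not in ASPECT_TO_NAMESPACE:
            raise ValueError(f"aspect must be one of F/P/C, got {self.aspect!r}")
        if not self.evidence_code or self.evidence_code != self.evidence_code.upper():
            raise ValueError(
                f"evidence code must be a non-empty uppercase token, got "
                f"{self.evidence_code!r}"
            )

    @property
    def negated(self) -> bool:
        """True when the annotation is NOT-qualified."""
        return "NOT" in self.qualifier


@dataclass
class OntologyGraph:
    """A DAG of ontology terms connected by ``is_a`` edges.

    ``graph`` holds child -> parent edges. ``namespace`` maps each term
    to its sub-ontology (MF/BP/CC); terms whose stanza lacked a
    namespace are absent from this map and excluded from depth queries.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    names: dict[str, str] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)
    alt_id: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def resolve(self, term: str) -> str:
        """Map an alternate id to its primary id (identity otherwise)."""
        return self.alt_id.get(term, term)

    def roots(self, namespace: str | None = None) -> set[str]:
        """Terms with no parent within their own namespace."""
        out = set()
        for t in self.graph.nodes:
            ns = self.namespace.get(t)
            if namespace is not None and ns != namespace:
                continue
            if not any(self.namespace.get(p) == ns for p in self.graph.successors(t)):
                out.add(t)
        return out


def _as_lines(stream: IO[str] | Iterable[str] | str) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(io.StringIO(stream))
    return iter(stream)


def parse_gaf(stream: IO[str] | Iterable[str] | str) -> list[AnnotationRecord]:
    """Parse a GAF 2.x stream into annotation records.

    Comment lines (``!`` prefix) and blank lines are skipped. Lines with
    fewer than 15 tab-separated columns, invalid GO ids or unknown
    aspect letters are skipped with a counted warning — annotation
    corpora are dirty and a single bad line must not abort a run.

    Raises
    ------
    EmptyInputError
        If no line yields a record (and none was skipped as malformed
        while at least one data line was seen -- an entirely
        comment/blank stream also raises).
    """
    records: list[AnnotationRecord] = []
    n_malformed = 0
    n_data_lines = 0
    for line in _as_lines(stream):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        n_data_lines += 1
        cols = line.split("\t")
        if len(cols) < 15:
            n_malformed += 1
            continue
        qualifier = tuple(q for q in cols[3].split("|") if q)
        try:
            records.append(
                AnnotationRecord(
                    db=cols[0],
                    db_object_id=cols[1],
                    go_id=cols[4],
                    qualifier=qualifier,
                    aspect=cols[8],
                    evidence_code=cols[6],
                    taxon=cols[12] if len(cols) > 12 else "",
                )
            )
        except ValueError as exc:
            n_malformed += 1
            logger.warning("skipping GAF line: %s", exc)
    if n_malformed:
        logger.warning("skipped %d malformed GAF line(s)", n_malformed)
    if n_data_lines == 0 or not records:
        raise EmptyInputError("GAF stream contains no parseable annotation lines")
    return records


def write_gaf(records: list[AnnotationRecord], stream: IO[str]) -> None:
    """Write records as GAF 2.0. ``parse_gaf`` round-trips all held fields."""
    stream.write(GAF_HEADER + "\n")
    for rec in records:
        cols = [""] * _GAF_NCOL
        cols[0] = rec.db
        cols[1] = rec.db_object_id
        cols[2] = rec.db_object_id  # symbol: not modelled, reuse object id
        cols[3] = "|".join(rec.qualifier)
        cols[4] = rec.go_id
        cols[5] = "GO_REF:0000000"
        cols[6] = rec.evidence_code
        cols[8] = rec.aspect
        cols[12] = rec.taxon
        cols[13] = "20091001"
        cols[14] = rec.db or "gozipf"
        stream.write("\t".join(cols) + "\n")


def parse_obo(stream: IO[str] | Iterable[str] | str) -> OntologyGraph:
    """Parse an OBO 1.2 stream into an :class:`OntologyGraph`.

    Non-obsolete terms become nodes; only ``is_a`` edges are kept.
    Alternate ids are mapped to their primary term. Terms without a
    recognised namespace are retained in the graph but excluded from
    the namespace map (hence from depth queries), with a warning.

    Raises
    ------
    OntologyStructureError
        If the ``is_a`` relation is cyclic (one cycle member is named).
    EmptyInputError
        If no term stanza is found.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    elif not hasattr(stream, "read"):
        stream = io.StringIO("".join(stream))
    multigraph = obonet.read_obo(stream, ignore_obsolete=False)
    if multigraph.number_of_nodes() == 0:
        raise EmptyInputError("OBO stream contains no term stanzas")

    out = OntologyGraph()
    for term, data in multigraph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            out.obsolete.add(term)
            continue
        out.graph.add_node(term)
        if "name" in data:
            out.names[term] = data["name"]
        ns = OBO_NAMESPACES.get(data.get("namespace", ""))
        if ns is None:
            logger.warning("term %s has no recognised namespace; "
                           "excluded from depth queries", term)
        else:
            out.namespace[term] = ns
        for alt in data.get("alt_id", []):
            out.alt_id[alt] = term
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if child in out.obsolete or parent in out.obsolete:
            continue
        out.graph.add_edge(child, parent)

    try:
        cycle = nx.find_cycle(out.graph)
    except nx.NetworkXNoCycle:
        pass
    else:
        raise OntologyStructureError(
            f"is_a relation is cyclic; cycle includes term {cycle[0][0]}"
        )
    return out
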