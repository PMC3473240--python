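import io

import pytest
from hypothesis import given, settings, strategies as st

from gozipf.ontology_io import (
    AnnotationRecord,
    EmptyInputError,
    OntologyStructureError,
    parse_gaf,
    parse_obo,
    write_gaf,
)
from tests.conftest import DIAMOND_OBO, gaf_line


class TestParseGaf:
    def test_single_line_fields(self):
        recs = parse_gaf([gaf_line()])
        assert len(recs) == 1
        r = recs[0]
        assert r.go_id == "GO:0008305"
        assert r.evidence_code == "IDA"
        assert r.aspect == "C"
        assert r.db == "UniProtKB"
        assert r.db_object_id == "P05556"

    def test_comments_and_blanks_skipped(self):
        recs = parse_gaf(["!gaf-version: 2.0", "", gaf_line(), "! comment"])
        assert len(recs) == 1

    def test_not_qualifier_parsed(self):
        recs = parse_gaf([gaf_line(qualifier="NOT")])
        assert recs[0].qualifier == ("NOT",)
        assert recs[0].negated

    def test_multi_qualifier_split_on_pipe(self):
        recs = parse_gaf([gaf_line(qualifier="NOT|contributes_to")])
        assert recs[0].qualifier == ("NOT", "contributes_to")

    def test_short_and_bad_lines_skipped_not_fatal(self, caplog):
        lines = [gaf_line(), "too\tfew\tcolumns",
                 gaf_line(aspect="X"), gaf_line(go_id="BAD:0000001")]
        with caplog.at_level("WARNING"):
            recs = parse_gaf(lines)
        assert len(recs) == 1
        assert "skipped 3 malformed" in caplog.text

    @pytest.mark.parametrize("lines", [[], ["!only a comment"], ["a\tb"]])
    def test_zero_parseable_lines_is_an_error(self, lines):
        with pytest.raises(EmptyInputError):
            parse_gaf(lines)


class TestRecordValidation:
    def test_go_id_pattern_enforced(self):
        with pytest.raises(ValueError):
            AnnotationRecord("db", "g", "GO:123", (), "C", "IDA")

    def test_aspect_must_be_fpc(self):
        with pytest.raises(ValueError):
            AnnotationRecord("db", "g", "GO:0000001", (), "Z", "IDA")

    def test_evidence_must_be_uppercase_token(self):
        with pytest.raises(ValueError):
            AnnotationRecord("db", "g", "GO:0000001", (), "C", "ida")
        with pytest.raises(ValueError):
            AnnotationRecord("db", "g", "GO:0000001", (), "C", "")


class TestWriteGaf:
    def test_empty_records_give_header_only(self):
        buf = io.StringIO()
        write_gaf([], buf)
        assert buf.getvalue() == "!gaf-version: 2.0\n"

    def test_not_qualifier_round_trips_in_column_4(self):
        rec = AnnotationRecord("db", "g", "GO:0000001", ("NOT",), "C", "IDA")
        buf = io.StringIO()
        write_gaf([rec], buf)
        data_line = buf.getvalue().splitlines()[1]
        assert data_line.split("\t")[3] == "NOT"


records_strategy = st.lists(
    st.builds(
        AnnotationRecord,
        db=st.sampled_from(["UniProtKB", "MGI", "SGD"]),
        db_object_id=st.text(
            alphabet=st.characters(whitelist_categories=("Lu", "Nd")),
            min_size=1, max_size=8,
        ),
        go_id=st.integers(0, 9_999_999).map(lambda i: f"GO:{i:07d}"),
        qualifier=st.sets(st.sampled_from(["NOT", "contributes_to"])).map(
            lambda s: tuple(sorted(s))
        ),
        aspect=st.sampled_from(["F", "P", "C"]),
        evidence_code=st.sampled_from(["IDA", "IEA", "TAS", "ISS", "IMP"]),
        taxon=st.sampled_from(["", "taxon:9606", "taxon:10090"]),
    ),
    max_size=20,
)


@given(records=records_strategy)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_gaf_write_parse_round_trip(records):
    """parse(write(records)) preserves every held field."""
    buf = io.StringIO()
    write_gaf(records, buf)
    buf.seek(0)
    if not records:
        with pytest.raises(EmptyInputError):
            parse_gaf(buf)
        return
    assert parse_gaf(buf) == records


class TestParseObo:
    def test_two_stanza_graph(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\n"
            "namespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: child\n"
            "namespace: biological_process\nis_a: GO:0000001\n"
        )
        g = parse_obo(text)
        assert g.terms == {"GO:0000001", "GO:0000002"}
        assert g.parents("GO:0000002") == {"GO:0000001"}
        assert g.namespace["GO:0000002"] == "BP"
        assert g.roots("BP") == {"GO:0000001"}

    def test_obsolete_terms_excluded(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: live\n"
            "namespace: molecular_function\n\n"
            "[Term]\nid: GO:0000002\nname: dead\n"
            "namespace: molecular_function\nis_obsolete: true\n"
        )
        g = parse_obo(text)
        assert "GO:0000002" in g.obsolete
        assert "GO:0000002" not in g.terms

    def test_alt_id_resolves_to_primary(self, diamond_graph):
        assert diamond_graph.resolve("GO:0000099") == "GO:0000006"
        assert diamond_graph.resolve("GO:0000006") == "GO:0000006"

    def test_term_without_namespace_excluded_from_namespace_map(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: orphan\n"
        )
        g = parse_obo(text)
        assert "GO:0000001" in g.terms
        assert "GO:0000001" not in g.namespace

    def test_cyclic_is_a_raises_naming_a_member(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\n"
            "namespace: molecular_function\nis_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nname: b\n"
            "namespace: molecular_function\nis_a: GO:0000001\n"
        )
        with pytest.raises(OntologyStructureError, match="GO:000000"):
            parse_obo(text)

    def test_empty_stream_is_an_error(self):
        with pytest.raises(EmptyInputError):
            parse_obo("format-version: 1.2\n")

    def test_diamond_fixture_shape(self, diamond_graph):
        assert len(diamond_graph.terms) == 6
        assert diamond_graph.parents("GO:0000006") == {"GO:0000002", "GO:0000005"}
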