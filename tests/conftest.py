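import pytest

from gozipf.ontology_io import AnnotationRecord, parse_obo


def gaf_line(go_id="GO:0008305", evidence="IDA", aspect="C", qualifier="",
             db="UniProtKB", obj="P05556", taxon="taxon:9606"):
    cols = [""] * 17
    cols[0] = db
    cols[1] = obj
    cols[2] = obj
    cols[3] = qualifier
    cols[4] = go_id
    cols[5] = "PMID:1"
    cols[6] = evidence
    cols[8] = aspect
    cols[12] = taxon
    cols[13] = "20091001"
    cols[14] = "UniProt"
    return "\t".join(cols)


@pytest.fixture
def mixed_records():
    """Records spanning all aspects and the HC/LC/neither evidence split."""
    return [
        AnnotationRecord("db", "g1", "GO:0000001", (), "C", "IDA"),
        AnnotationRecord("db", "g2", "GO:0000002", (), "C", "IEA"),
        AnnotationRecord("db", "g3", "GO:0000003", (), "C", "ISS"),
        AnnotationRecord("db", "g4", "GO:0000004", (), "F", "TAS"),
        AnnotationRecord("db", "g5", "GO:0000005", (), "F", "IEA"),
        AnnotationRecord("db", "g6", "GO:0000006", (), "P", "IMP"),
        AnnotationRecord("db", "g7", "GO:0000001", ("NOT",), "C", "IDA"),
    ]


DIAMOND_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: shallow parent
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: mid a
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000004
name: mid b
namespace: molecular_function
is_a: GO:0000003

[Term]
id: GO:0000005
name: mid c
namespace: molecular_function
is_a: GO:0000004

[Term]
id: GO:0000006
name: bottom, two paths: via 2 (short) and via 5 (long)
namespace: molecular_function
alt_id: GO:0000099
is_a: GO:0000002
is_a: GO:0000005
"""


@pytest.fixture
def diamond_graph():
    """MF diamond: depth(GO:0000006) is 2 via the short arm, 4 via the long."""
    return parse_obo(DIAMOND_OBO)
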