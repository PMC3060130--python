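"""ACS container packing, validation completeness, and the relation graph."""

import zipfile
import io

import numpy as np
import pytest

from cytostd.acs import (
    ACSContainer,
    Finding,
    TocRelation,
    containers_equal,
    derived_from,
    pack,
    toc_to_graph,
    unpack,
    validate,
)
from cytostd.errors import FormatError, IntegrityError
from cytostd.fcs import make_dataset, write_fcs


def small_container():
    c = ACSContainer()
    fcs_bytes = write_fcs(make_dataset(np.ones((5, 2)), ["A", "B"]))
    c.add_member("fcs/raw.fcs", fcs_bytes, "application/vnd.isac.fcs", role="raw")
    c.add_member("fcs/pre.fcs", fcs_bytes, "application/vnd.isac.fcs", role="pre")
    c.add_member("clr/res.csv", b"a,b\r\n1,0\r\n", "text/csv", role="clr")
    c.relate("fcs/pre.fcs", "preprocessed-from", "fcs/raw.fcs")
    c.relate("clr/res.csv", "classification-results-of", "fcs/pre.fcs")
    return c


class TestPackUnpack:
    def test_roundtrip_identity(self):
        c = small_container()
        assert containers_equal(unpack(pack(c)), c)

    def test_opens_with_stock_zip_tooling(self):
        raw = pack(small_container())
        with zipfile.ZipFile(io.BytesIO(raw)) as zf:
            assert zf.testzip() is None
            assert "TOC.xml" in zf.namelist()
            assert len(zf.namelist()) == 4  # 3 members + ToC

    def test_empty_container_roundtrips(self):
        c = ACSContainer()
        assert containers_equal(unpack(pack(c)), c)

    def test_pack_is_deterministic(self):
        assert pack(small_container()) == pack(small_container())

    def test_missing_toc_is_format_error(self):
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            zf.writestr("data.bin", b"x")
        with pytest.raises(FormatError, match="TOC"):
            unpack(buf.getvalue())

    def test_not_a_zip(self):
        with pytest.raises(FormatError, match="ZIP"):
            unpack(b"definitely not a zip archive")

    def test_entry_without_bytes_cannot_pack(self):
        c = small_container()
        del c.members["clr/res.csv"]
        with pytest.raises(IntegrityError, match="clr/res.csv"):
            pack(c)

    def test_signature_blocks_roundtrip(self):
        c = small_container()
        c.signature_blocks.append(b'<sig xmlns="urn:x">opaque</sig>')
        c2 = unpack(pack(c))
        assert len(c2.signature_blocks) == 1
        assert b"opaque" in c2.signature_blocks[0]


class TestValidate:
    def test_consistent_container_is_clean(self):
        assert validate(small_container()) == []

    def test_corrupt_member_byte_detected(self):
        c = small_container()
        data = bytearray(c.members["fcs/raw.fcs"])
        data[100] ^= 0xFF
        c.members["fcs/raw.fcs"] = bytes(data)
        findings = [f for f in validate(c) if f.level == "error"]
        assert len(findings) == 1
        assert findings[0].code == "CHECKSUM_MISMATCH"
        assert "fcs/raw.fcs" in findings[0].message

    def test_dangling_relation_detected(self):
        c = small_container()
        c.relations.append(TocRelation("clr/res.csv", "ghost.fcs", "derived-from"))
        codes = [f.code for f in validate(c)]
        assert codes.count("DANGLING_RELATION") == 1

    def test_orphan_member_is_warning(self):
        c = small_container()
        c.members["stray.bin"] = b"x"
        findings = validate(c)
        assert [f.code for f in findings] == ["ORPHAN_MEMBER"]
        assert findings[0].level == "warning"

    def test_removed_member_detected(self):
        c = small_container()
        del c.members["fcs/pre.fcs"]
        assert any(f.code == "DANGLING_ENTRY" for f in validate(c))

    def test_unknown_relationship_is_warning(self):
        c = small_container()
        c.relate("fcs/raw.fcs", "frobnicated-by", "clr/res.csv")
        assert any(f.code == "UNKNOWN_RELATIONSHIP" and f.level == "warning"
                   for f in validate(c))

    def test_missing_version_is_warning(self):
        c = small_container()
        c.version = None
        assert any(f.code == "MISSING_VERSION" for f in validate(c))

    @pytest.mark.parametrize("mutation", ["remove_member", "remove_entry",
                                          "corrupt_byte", "dangle_relation"])
    def test_every_mutation_class_yields_a_finding(self, mutation):
        """Validation completeness over the four structural mutations."""
        c = small_container()
        if mutation == "remove_member":
            del c.members["clr/res.csv"]
        elif mutation == "remove_entry":
            c.entries = [e for e in c.entries if e.uri != "clr/res.csv"]
        elif mutation == "corrupt_byte":
            c.members["clr/res.csv"] = b"a,b\r\n0,0\r\n"
        else:
            c.relations.append(TocRelation("nope", "clr/res.csv", "derived-from"))
        assert len(validate(c)) >= 1


class TestGraph:
    def test_two_edge_chain_closure(self):
        c = small_container()
        closure = derived_from(c, "fcs/raw.fcs")
        assert closure == {"fcs/pre.fcs", "clr/res.csv"}

    def test_nodes_match_entries_and_empty_relations(self):
        c = small_container()
        c.relations = []
        g = toc_to_graph(c)
        assert set(g.nodes) == {e.uri for e in c.entries}
        assert g.number_of_edges() == 0

    def test_example_lineage_unambiguous(self, example_acs_path):
        """Each CLR file in the example traces back to exactly one raw FCS."""
        c = unpack(example_acs_path)
        g = toc_to_graph(c)
        raws = [e.uri for e in c.entries if e.role == "raw FCS data file"]
        for e in c.entries:
            if e.role == "classification results":
                import networkx as nx

                reach = nx.descendants(g, e.uri)
                assert len(reach & set(raws)) == 1
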