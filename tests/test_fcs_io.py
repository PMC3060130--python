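"""FCS header/TEXT parsing and binary round-trip behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytostd.errors import FormatError, UnsupportedFeatureError, ValidationError
from cytostd.fcs import (
    FCSDataset,
    KeywordMap,
    make_dataset,
    parse_header,
    parse_text_segment,
    read_fcs,
    serialize_text_segment,
    write_fcs,
)

from conftest import random_dataset


def _header(version=b"FCS3.1", fields=("58", "1000", "1001", "5000", "0", "0")):
    out = version + b" " * 4
    for f in fields:
        out += b" " * (8 - len(f)) + f.encode()
    return out


class TestHeader:
    def test_direct_field_read(self):
        offs = parse_header(_header())
        assert offs.version_string == "FCS3.1"
        assert (offs.text_begin, offs.text_end) == (58, 1000)
        assert (offs.data_begin, offs.data_end) == (1001, 5000)

    def test_non_fcs_magic_names_observed_bytes(self):
        with pytest.raises(FormatError, match="XYZ3.1"):
            parse_header(_header(version=b"XYZ3.1"))

    def test_non_numeric_offset_reports_position(self):
        with pytest.raises(FormatError, match="byte 18"):
            parse_header(_header(fields=("58", "10xx", "0", "0", "0", "0")))

    def test_31_version_accepted_and_roundtrips(self):
        ds = make_dataset(np.ones((3, 2)), ["A", "B"])
        raw = write_fcs(ds)
        offs = parse_header(raw)
        assert offs.version_string == "FCS3.1"
        reread = read_fcs(raw)
        assert reread.offsets.version_string == "FCS3.1"
        # the header offsets written are the ones parsed back
        assert raw[offs.text_begin] == raw[offs.text_begin]  # slice is valid
        assert offs.text_begin == 58


class TestTextSegment:
    def test_two_pairs(self):
        kw = parse_text_segment(b"/$MODE/L/$PAR/2/")
        assert dict(kw) == {"$MODE": "L", "$PAR": "2"}

    def test_doubled_delimiter_unescapes(self):
        kw = parse_text_segment(b"/K/a//b/")
        assert dict(kw) == {"K": "a/b"}

    def test_odd_token_count_rejected(self):
        with pytest.raises(FormatError, match="odd"):
            parse_text_segment(b"/$MODE/L/$PAR/")

    def test_duplicate_standard_keyword_rejected(self):
        with pytest.raises(FormatError, match=r"\$MODE"):
            parse_text_segment(b"/$MODE/L/$mode/L/")

    def test_dollar_keywords_uppercased_user_keys_verbatim(self):
        kw = parse_text_segment(b"/$par/2/MyKey/v/")
        assert "$PAR" in kw and kw["$PAR"] == "2"
        assert list(kw) == ["$PAR", "MyKey"]

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.text(
                alphabet=st.characters(
                    min_codepoint=33, max_codepoint=126, exclude_characters="$"
                ),
                min_size=1, max_size=12,
            ).filter(lambda k: not (k.startswith("/") or k.endswith("/"))),
            st.text(
                alphabet=st.characters(min_codepoint=32, max_codepoint=0x2FF),
                min_size=1, max_size=20,
            ).filter(lambda v: not (v.startswith("/") or v.endswith("/"))),
            min_size=1, max_size=12,
        )
    )
    def test_serialize_parse_roundtrip(self, mapping):
        """Serializer-defined oracle: parse(serialize(m)) == m, incl. escapes."""
        kw = KeywordMap(mapping)
        assert parse_text_segment(serialize_text_segment(kw)) == kw

    def test_empty_value_forbidden(self):
        with pytest.raises(ValidationError):
            KeywordMap({"K": ""})


class TestReadWrite:
    def test_float_values_roundtrip(self):
        ds = make_dataset(
            np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]), ["A", "B"]
        )
        out = read_fcs(write_fcs(ds, datatype="F"))
        assert out.n_events == 3 and out.n_parameters == 2
        np.testing.assert_array_equal(out.events, ds.events)

    def test_integer_masking_to_pnr(self):
        """$PnB 16 / $PnR 1024: stored 0xFFFF decodes to 0xFFFF & 0x03FF."""
        ds = make_dataset(np.array([[1023.0]]), ["A"], ranges=1024.0)
        ds.parameters[0].bits = 16
        raw = bytearray(write_fcs(ds, datatype="I"))
        # patch the 2 stored data bytes (just before the 8-byte CRC) to 0xFFFF
        raw[-10:-8] = b"\xff\xff"
        out = read_fcs(bytes(raw))
        assert out.events[0, 0] == 0xFFFF & 0x03FF == 1023

    @pytest.mark.parametrize("datatype", ["F", "D", "I"])
    @pytest.mark.parametrize("byte_order", ["little", "big"])
    def test_roundtrip_all_datatypes_and_orders(self, rng, datatype, byte_order):
        ds = random_dataset(rng, n_events=500, n_params=7, datatype=datatype)
        out = read_fcs(write_fcs(ds, datatype=datatype, byte_order=byte_order))
        if datatype == "F":
            np.testing.assert_allclose(out.events, ds.events, rtol=1e-6, atol=0)
        else:
            np.testing.assert_array_equal(out.events, ds.events)

    def test_endianness_invariance(self, rng):
        ds = random_dataset(rng, n_events=200, n_params=4, datatype="D")
        little = read_fcs(write_fcs(ds, datatype="D", byte_order="little"))
        big = read_fcs(write_fcs(ds, datatype="D", byte_order="big"))
        np.testing.assert_array_equal(little.events, big.events)

    def test_synthetic_pbmc_channel_names(self, synth_sample):
        out = read_fcs(write_fcs(synth_sample.dataset))
        assert out.n_parameters == 10
        assert out.channel_names == [
            "FSC-A", "SSC-A", "CD123", "CD11c", "MHC-II", "CD14",
            "IL-6", "IL-12", "TNF-a", "IFN-a",
        ]

    def test_31_annotation_keywords_preserved(self):
        ds = make_dataset(
            np.ones((2, 2)), ["A", "B"],
            extra_keywords={
                "$ORIGINALITY": "Original", "$PLATEID": "P1",
                "$WELLID": "A01", "$VOL": "50000",
            },
        )
        out = read_fcs(write_fcs(ds))
        assert out.keywords["$ORIGINALITY"] == "Original"
        assert out.keywords["$PLATEID"] == "P1"
        assert out.keywords["$WELLID"] == "A01"
        assert out.keywords["$VOL"] == "50000"

    def test_empty_dataset_roundtrips(self):
        ds = make_dataset(np.empty((0, 2)), ["A", "B"])
        out = read_fcs(write_fcs(ds))
        assert out.keywords["$TOT"] == "0"
        assert out.events.shape == (0, 2)

    def test_display_and_stain_keywords_roundtrip(self):
        ds = make_dataset(np.ones((1, 1)), ["CD4"], stain_names=["CD4 PE"])
        ds.parameters[0].display = ("Logarithmic", (4.0, 1.0))
        out = read_fcs(write_fcs(ds))
        assert out.parameters[0].stain_name == "CD4 PE"
        assert out.parameters[0].display == ("Logarithmic", (4.0, 1.0))

    def test_ascii_datatype_rejected(self):
        ds = make_dataset(np.ones((1, 1)), ["A"])
        with pytest.raises(UnsupportedFeatureError, match="ASCII"):
            write_fcs(ds, datatype="A")

    def test_non_list_mode_rejected(self):
        ds = make_dataset(np.ones((1, 1)), ["A"])
        raw = write_fcs(ds).replace(b"$MODE/L/", b"$MODE/U/")
        with pytest.raises(UnsupportedFeatureError, match="list mode"):
            read_fcs(raw)

    def test_truncated_data_reports_byte_counts(self):
        ds = make_dataset(np.ones((10, 2)), ["A", "B"])
        raw = write_fcs(ds)
        with pytest.raises(FormatError, match="expected 80"):
            read_fcs(raw[:-48])  # drop CRC + half the data

    def test_tot_mismatch_is_validation_error(self):
        ds = make_dataset(np.ones((3, 1)), ["A"])
        ds.keywords["$TOT"] = "4"
        with pytest.raises(ValidationError):
            write_fcs(ds)

    def test_large_offsets_move_to_text(self):
        """>8-digit DATA offsets are carried by $BEGINDATA/$ENDDATA."""
        # 1.6M events x 8 params x 8 bytes ~= 102 MB > the 99,999,999 limit
        ds = make_dataset(
            np.zeros((1_600_000, 8)), [f"CH{i}" for i in range(8)]
        )
        raw = write_fcs(ds, datatype="D")
        offs = parse_header(raw)
        assert offs.data_begin == 0 and offs.data_end == 0
        out = read_fcs(raw)
        assert int(out.keywords["$ENDDATA"]) > 99_999_999
        assert out.events.shape == (1_600_000, 8)
        assert not out.events.any()

    def test_dataset_index_out_of_range(self):
        ds = make_dataset(np.ones((1, 1)), ["A"])
        with pytest.raises(FormatError, match="chain ended"):
            read_fcs(write_fcs(ds), dataset_index=1)
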