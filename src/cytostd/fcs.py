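"""Reading and writing FCS list-mode data files.

FCS is the binary container in which flow cytometers store one row of
channel intensities per measured event.  A file is laid out as a 58-byte
ASCII HEADER (version tag plus byte offsets), a delimited TEXT segment of
keyword/value pairs, a binary DATA segment, and an optional ANALYSIS
segment.  This module reads versions 2.0/3.0/3.1 and writes 3.1, the
current revision, which added keywords for stored compensation
($SPILLOVER), preferred display scale ($PnD), sample volume ($VOL),
data-file originality tracking ($ORIGINALITY) and plate/well
identification ($PLATEID, $PLATENAME, $WELLID).

Only list mode ($MODE L) is supported; the deprecated ASCII datatype is
rejected.  Written files use a single dataset, the "/" delimiter, and
UTF-8 TEXT; readers fall back to Latin-1 for undecodable bytes.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterator, MutableMapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, UnsupportedFeatureError, ValidationError

__all__ = [
    "SegmentOffsets",
    "KeywordMap",
    "ParameterDescriptor",
    "FCSDataset",
    "parse_header",
    "parse_text_segment",
    "serialize_text_segment",
    "read_fcs",
    "write_fcs",
]

HEADER_LEN = 58
DEFAULT_DELIMITER = b"/"

#: number of bytes per value for each written $DATATYPE
_DTYPE_CODES = {"F": "f4", "D": "f8", "I": "u"}


@dataclass(frozen=True)
class SegmentOffsets:
    """Byte offsets parsed from the 58-byte ASCII header.

    Offsets are inclusive on both ends, as the format defines them; a
    value of 0 means the segment is absent or its offsets live in TEXT
    ($BEGINDATA/$ENDDATA).
    """

    version_string: str
    text_begin: int
    text_end: int
    data_begin: int = 0
    data_end: int = 0
    analysis_begin: int = 0
    analysis_end: int = 0

    def __post_init__(self) -> None:
        if not self.version_string.startswith("FCS"):
            raise FormatError(
                f"not an FCS header: version tag {self.version_string!r}"
            )
        for name in ("text", "data", "analysis"):
            lo = getattr(self, f"{name}_begin")
            hi = getattr(self, f"{name}_end")
            if lo < 0 or hi < 0:
                raise FormatError(f"negative {name} offsets ({lo}, {hi})")
        if self.text_end < self.text_begin:
            raise FormatError(
                f"TEXT end {self.text_end} precedes begin {self.text_begin}"
            )


class KeywordMap(MutableMapping):
    """Ordered keyword -> value mapping with FCS lookup semantics.

    Keys beginning with ``$`` (the standard keywords) are matched
    case-insensitively and stored upper-cased; user keywords are stored
    and matched verbatim.  Empty values are rejected, as the format
    forbids them.
    """

    def __init__(self, items=None):
        self._d: dict[str, str] = {}
        if items:
            pairs = items.items() if hasattr(items, "items") else items
            for k, v in pairs:
                self[k] = v

    @staticmethod
    def _norm(key: str) -> str:
        return key.upper() if key.startswith("$") else key

    def __setitem__(self, key: str, value: str) -> None:
        if not isinstance(value, str):
            value = str(value)
        if value == "":
            raise ValidationError(f"keyword {key!r} has an empty value")
        self._d[self._norm(key)] = value

    def __getitem__(self, key: str) -> str:
        return self._d[self._norm(key)]

    def __delitem__(self, key: str) -> None:
        del self._d[self._norm(key)]

    def __iter__(self) -> Iterator[str]:
        return iter(self._d)

    def __len__(self) -> int:
        return len(self._d)

    def __repr__(self) -> str:
        return f"KeywordMap({self._d!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, KeywordMap):
            return self._d == other._d
        return dict(self) == dict(other) if isinstance(other, dict) else NotImplemented


@dataclass
class ParameterDescriptor:
    """Per-channel metadata: $PnN/$PnS/$PnB/$PnE/$PnR/$PnD for one n."""

    index: int  # 1-based
    short_name: str  # $PnN
    bits: int  # $PnB
    amplification: tuple[float, float] = (0.0, 0.0)  # $PnE (decades, offset)
    range: float = 262144.0  # $PnR
    stain_name: str | None = None  # $PnS
    display: tuple[str, tuple[float, ...]] | None = None  # $PnD

    def __post_init__(self) -> None:
        if self.amplification[0] < 0:
            raise ValidationError(
                f"parameter {self.index}: $PnE decades must be >= 0"
            )
        if self.range <= 0:
            raise ValidationError(f"parameter {self.index}: $PnR must be > 0")


@dataclass
class FCSDataset:
    """One list-mode dataset: keywords, parameter descriptors and events.

    ``events`` is an (n_events, n_parameters) float64 matrix whose column
    order matches the 1-based parameter index order.
    """

    keywords: KeywordMap
    parameters: list[ParameterDescriptor]
    events: np.ndarray
    offsets: SegmentOffsets | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValidationError("event matrix must be 2-D")
        if self.events.shape[1] != len(self.parameters):
            raise ValidationError(
                f"event matrix has {self.events.shape[1]} columns but "
                f"{len(self.parameters)} parameter descriptors"
            )

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.events.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [p.short_name for p in self.parameters]

    def channel_index(self, name: str) -> int:
        """0-based column index of the channel with $PnN == name."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            from .errors import ChannelError

            raise ChannelError(
                f"no channel named {name!r}; available $PnN values: "
                f"{', '.join(self.channel_names)}"
            ) from None

    def channel_data(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]


def make_dataset(
    events: np.ndarray,
    channel_names: list[str],
    ranges: list[float] | float = 262144.0,
    extra_keywords: dict | None = None,
    stain_names: list[str | None] | None = None,
) -> FCSDataset:
    """Convenience constructor building descriptors and required keywords."""
    events = np.asarray(events, dtype=np.float64)
    n_par = events.shape[1]
    if np.isscalar(ranges):
        ranges = [float(ranges)] * n_par
    params = [
        ParameterDescriptor(
            index=i + 1,
            short_name=channel_names[i],
            bits=32,
            amplification=(0.0, 0.0),
            range=ranges[i],
            stain_name=stain_names[i] if stain_names else None,
        )
        for i in range(n_par)
    ]
    kw = KeywordMap(
        {
            "$MODE": "L",
            "$DATATYPE": "F",
            "$BYTEORD": "1,2,3,4",
            "$PAR": str(n_par),
            "$TOT": str(events.shape[0]),
        }
    )
    if extra_keywords:
        for k, v in extra_keywords.items():
            kw[k] = v
    return FCSDataset(keywords=kw, parameters=params, events=events)


# ---------------------------------------------------------------------------
# HEADER
# ---------------------------------------------------------------------------

def parse_header(raw: bytes, at: int = 0) -> SegmentOffsets:
    """Parse the 58-byte ASCII header starting at byte ``at``.

    Offsets of 0 in the header mean "see $BEGINDATA/$ENDDATA in TEXT".
    """
    if len(raw) - at < HEADER_LEN:
        raise FormatError(
            f"file too short for an FCS header: {len(raw) - at} bytes"
        )
    tag = raw[at : at + 6]
    if not tag.startswith(b"FCS"):
        raise FormatError(f"not an FCS file: first 6 bytes are {tag!r}")
    fields = []
    for i in range(6):
        lo = at + 10 + 8 * i
        chunk = raw[lo : lo + 8].strip()
        if chunk == b"":
            fields.append(0)
            continue
        try:
            fields.append(int(chunk))
        except ValueError:
            raise FormatError(
                f"non-numeric header offset field {chunk!r} at byte {lo}"
            ) from None
    return SegmentOffsets(tag.decode("ascii"), *fields)


def _decode_text(raw: bytes) -> str:
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        warnings.warn(
            "TEXT segment is not valid UTF-8; falling back to Latin-1",
            stacklevel=3,
        )
        return raw.decode("latin-1")


def parse_text_segment(raw: bytes) -> KeywordMap:
    """Parse a TEXT (or supplemental TEXT) segment into a KeywordMap.

    The first byte is the delimiter.  A delimiter doubled inside a value
    escapes one literal delimiter character.
    """
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # a trailing delimiter terminates the last value
    if body.endswith(delim):
        body = body[:-1]
    elif body.strip() == b"":
        return KeywordMap()
    # greedy scan: a doubled delimiter is one escaped literal delimiter
    tokens: list[bytes] = []
    cur = bytearray()
    i, n = 0, len(body)
    while i < n:
        if body[i : i + 1] == delim:
            if body[i + 1 : i + 2] == delim:
                cur += delim
                i += 2
                continue
            tokens.append(bytes(cur))
            cur = bytearray()
        else:
            cur.append(body[i])
        i += 1
    tokens.append(bytes(cur))
    if len(tokens) % 2 != 0:
        raise FormatError(
            f"TEXT segment has an odd number of tokens ({len(tokens)}); "
            "keyword/value pairs are incomplete"
        )
    kw = KeywordMap()
    for i in range(0, len(tokens), 2):
        key = _decode_text(tokens[i]).strip()
        value = _decode_text(tokens[i + 1])
        norm = KeywordMap._norm(key)
        if norm.startswith("$") and norm in kw:
            raise FormatError(f"duplicate standard keyword {norm}")
        kw[key] = value
    return kw


def serialize_text_segment(kw: KeywordMap, delimiter: bytes = DEFAULT_DELIMITER) -> bytes:
    """Serialize a KeywordMap to TEXT bytes (delimiter-framed, escaped)."""
    if len(delimiter) != 1:
        raise ValidationError("delimiter must be a single byte")
    d = delimiter
    out = [d]
    for key, value in kw.items():
        for text, what in ((key, "keyword"), (value, "value")):
            tb = text.encode("utf-8")
            if tb.startswith(d) or tb.endswith(d):
                # the doubling escape cannot represent these unambiguously
                raise ValidationError(
                    f"{what} {text!r} starts or ends with the delimiter "
                    f"{d.decode('latin-1')!r}"
                )
        kb = key.encode("utf-8").replace(d, d + d)
        vb = value.encode("utf-8").replace(d, d + d)
        out.extend([kb, d, vb, d])
    return b"".join(out)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _byte_order(value: str) -> str:
    """Map $BYTEORD to a numpy byte-order character."""
    toks = value.replace(" ", "").split(",")
    if toks == sorted(toks):
        return "<"
    if toks == sorted(toks, reverse=True):
        return ">"
    raise UnsupportedFeatureError(f"mixed byte order {value!r} is not supported")


def _parameter_from_keywords(kw: KeywordMap, n: int) -> ParameterDescriptor:
    def req(suffix: str) -> str:
        key = f"$P{n}{suffix}"
        if key not in kw:
            raise FormatError(f"required keyword {key} missing")
        return kw[key]

    amp = req("E").split(",")
    if len(amp) != 2:
        raise FormatError(f"$P{n}E must be 'decades,offset', got {kw[f'$P{n}E']!r}")
    display = None
    if f"$P{n}D" in kw:
        toks = kw[f"$P{n}D"].split(",")
        display = (toks[0], tuple(float(t) for t in toks[1:]))
    return ParameterDescriptor(
        index=n,
        short_name=req("N"),
        bits=int(req("B")),
        amplification=(float(amp[0]), float(amp[1])),
        range=float(req("R")),
        stain_name=kw.get(f"$P{n}S"),
        display=display,
    )


def _int_mask(pnr: float) -> int:
    """Bit mask for stored integer data: next power of two above $PnR, minus 1."""
    if pnr <= 1:
        return 1
    return (1 << math.ceil(math.log2(pnr))) - 1


def _decode_events(raw: bytes, kw: KeywordMap, params: list[ParameterDescriptor]) -> np.ndarray:
    n_tot = int(kw["$TOT"])
    n_par = len(params)
    datatype = kw["$DATATYPE"].upper()
    order = _byte_order(kw["$BYTEORD"])
    if datatype == "A":
        raise UnsupportedFeatureError(
            "$DATATYPE A (ASCII) is deprecated in FCS 3.1 and not supported"
        )
    if datatype not in ("F", "D", "I"):
        raise FormatError(f"unknown $DATATYPE {datatype!r}")

    bits = [p.bits for p in params]
    if datatype == "F" and any(b != 32 for b in bits):
        raise FormatError("$DATATYPE F requires $PnB 32 for every parameter")
    if datatype == "D" and any(b != 64 for b in bits):
        raise FormatError("$DATATYPE D requires $PnB 64 for every parameter")
    if datatype == "I" and any(b not in (8, 16, 32, 64) for b in bits):
        raise UnsupportedFeatureError(
            "integer data with non-octet $PnB widths is not supported"
        )
    row_bytes = sum(bits) // 8
    expected = n_tot * row_bytes
    if len(raw) < expected:
        raise FormatError(
            f"DATA segment truncated: expected {expected} bytes "
            f"($TOT {n_tot} x {row_bytes} bytes/event), got {len(raw)}"
        )
    raw = raw[:expected]
    if n_tot == 0:
        return np.empty((0, n_par), dtype=np.float64)

    if datatype in ("F", "D"):
        dt = np.dtype(order + _DTYPE_CODES[datatype])
        mat = np.frombuffer(raw, dtype=dt).reshape(n_tot, n_par)
        return mat.astype(np.float64)

    # integer data: parameters may have heterogeneous widths
    fields = [(f"p{i}", np.dtype(order + f"u{b // 8}")) for i, b in enumerate(bits)]
    rec = np.frombuffer(raw, dtype=np.dtype(fields))
    out = np.empty((n_tot, n_par), dtype=np.float64)
    for i, p in enumerate(params):
        col = rec[f"p{i}"].astype(np.uint64)
        mask = _int_mask(p.range)
        if mask < (1 << p.bits) - 1:
            col = col & np.uint64(mask)
        out[:, i] = col
    return out


def _read_one(raw: bytes, at: int) -> tuple[FCSDataset, int]:
    """Read the dataset whose header starts at byte ``at``.

    Returns (dataset, next_offset) where next_offset is the absolute
    offset of the next dataset, or 0 if none.
    """
    offs = parse_header(raw, at)
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        kw = parse_text_segment(raw[at + offs.text_begin : at + offs.text_end + 1])
        collected.extend(str(w.message) for w in wrec)

    # supplemental TEXT
    sup_lo = int(kw.get("$BEGINSTEXT", "0"))
    sup_hi = int(kw.get("$ENDSTEXT", "0"))
    if sup_hi > sup_lo > 0 and (sup_lo, sup_hi) != (offs.text_begin, offs.text_end):
        sup = parse_text_segment(raw[at + sup_lo : at + sup_hi + 1])
        for k, v in sup.items():
            kw.setdefault(k, v)

    for req in ("$MODE", "$DATATYPE", "$BYTEORD", "$PAR", "$TOT"):
        if req not in kw:
            raise FormatError(f"required keyword {req} missing")
    if kw["$MODE"].upper() != "L":
        raise UnsupportedFeatureError(
            f"$MODE {kw['$MODE']!r} is not supported; only list mode (L)"
        )
    n_par = int(kw["$PAR"])
    params = [_parameter_from_keywords(kw, n + 1) for n in range(n_par)]

    data_lo, data_hi = offs.data_begin, offs.data_end
    if data_lo == 0:
        data_lo = int(kw.get("$BEGINDATA", "0"))
        data_hi = int(kw.get("$ENDDATA", "0"))
    events = _decode_events(raw[at + data_lo : at + data_hi + 1], kw, params)
    ds = FCSDataset(
        keywords=kw, parameters=params, events=events, offsets=offs,
        warnings=collected,
    )
    nxt = int(kw.get("$NEXTDATA", "0"))
    return ds, (at + nxt if nxt else 0)


def read_fcs(source: str | Path | bytes, dataset_index: int = 0) -> FCSDataset:
    """Read one list-mode dataset from an FCS 2.0/3.0/3.1 file.

    Parameters
    ----------
    source
        Path to a file, or the raw bytes of one.
    dataset_index
        Which dataset of a $NEXTDATA chain to read (0 = first).
    """
    raw = source if isinstance(source, (bytes, bytearray)) else Path(source).read_bytes()
    raw = bytes(raw)
    at = 0
    for _ in range(dataset_index):
        _, at = _read_one(raw, at)
        if at == 0:
            raise FormatError(
                f"dataset index {dataset_index} out of range: $NEXTDATA chain ended"
            )
    ds, _ = _read_one(raw, at)
    return ds


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_OFFSET_KEYWORDS = (
    "$BEGINDATA", "$ENDDATA", "$BEGINANALYSIS", "$ENDANALYSIS",
    "$BEGINSTEXT", "$ENDSTEXT", "$NEXTDATA",
)


def _encode_events(ds: FCSDataset, datatype: str, order: str) -> tuple[bytes, list[int]]:
    """Encode the event matrix; returns (bytes, per-parameter bit widths)."""
    if datatype == "F":
        return ds.events.astype(np.dtype(order + "f4")).tobytes(), [32] * ds.n_parameters
    if datatype == "D":
        return ds.events.astype(np.dtype(order + "f8")).tobytes(), [64] * ds.n_parameters
    if datatype == "I":
        bits, cols = [], []
        for i, p in enumerate(ds.parameters):
            b = p.bits if p.bits in (8, 16, 32, 64) else 32
            bits.append(b)
            col = np.round(ds.events[:, i]).astype(np.uint64)
            if (col > (1 << b) - 1).any():
                raise ValidationError(
                    f"parameter {p.short_name}: values exceed {b}-bit storage"
                )
            cols.append(col.astype(f"u{b // 8}"))
        rec = np.empty(
            ds.n_events,
            dtype=np.dtype([(f"p{i}", np.dtype(order + f"u{b // 8}"))
                            for i, b in enumerate(bits)]),
        )
        for i, col in enumerate(cols):
            rec[f"p{i}"] = col
        return rec.tobytes(), bits
    raise UnsupportedFeatureError(f"cannot write $DATATYPE {datatype!r}")


def write_fcs(
    ds: FCSDataset,
    datatype: str = "F",
    byte_order: str = "little",
    delimiter: bytes = DEFAULT_DELIMITER,
) -> bytes:
    """Serialize a dataset as a single-dataset FCS 3.1 byte string.

    When the DATA segment ends beyond the 8-digit header field limit the
    header offsets are written as 0 and $BEGINDATA/$ENDDATA (always
    present in TEXT, as 3.1 requires) carry the real values.
    """
    datatype = datatype.upper()
    if datatype == "A":
        raise UnsupportedFeatureError("$DATATYPE A (ASCII) is deprecated; use F, D or I")
    if int(ds.keywords.get("$TOT", ds.n_events)) != ds.n_events:
        raise ValidationError("$TOT disagrees with the event matrix")
    if int(ds.keywords.get("$PAR", ds.n_parameters)) != ds.n_parameters:
        raise ValidationError("$PAR disagrees with the parameter count")

    order = "<" if byte_order == "little" else ">"
    data, bits = _encode_events(ds, datatype, order)

    kw = KeywordMap()
    kw["$MODE"] = "L"
    kw["$DATATYPE"] = datatype
    kw["$BYTEORD"] = "1,2,3,4" if order == "<" else "4,3,2,1"
    kw["$PAR"] = str(ds.n_parameters)
    kw["$TOT"] = str(ds.n_events)
    for p, b in zip(ds.parameters, bits):
        n = p.index
        kw[f"$P{n}N"] = p.short_name
        kw[f"$P{n}B"] = str(b)
        amp = p.amplification if datatype == "I" else (0.0, 0.0)
        kw[f"$P{n}E"] = f"{amp[0]:g},{amp[1]:g}"
        kw[f"$P{n}R"] = f"{p.range:g}"
        if p.stain_name is not None:
            kw[f"$P{n}S"] = p.stain_name
        if p.display is not None:
            kw[f"$P{n}D"] = ",".join([p.display[0]] + [f"{v:g}" for v in p.display[1]])
    for k, v in ds.keywords.items():
        if k in _OFFSET_KEYWORDS:
            continue
        kw.setdefault(k, v)

    # TEXT length depends on the offset digits; iterate to a fixed point
    text_begin = HEADER_LEN
    data_begin, data_end = 0, 0
    for _ in range(8 if data else 1):
        kw["$BEGINSTEXT"] = "0"
        kw["$ENDSTEXT"] = "0"
        kw["$BEGINANALYSIS"] = "0"
        kw["$ENDANALYSIS"] = "0"
        kw["$NEXTDATA"] = "0"
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(data_end)
        text = serialize_text_segment(kw, delimiter)
        new_begin = text_begin + len(text)
        new_end = new_begin + max(len(data) - 1, 0)
        if (new_begin, new_end) == (data_begin, data_end):
            break
        data_begin, data_end = new_begin, new_end
    text_end = text_begin + len(text) - 1

    def hfield(v: int) -> bytes:
        s = str(v)
        return b" " * (8 - len(s)) + s.encode("ascii") if len(s) <= 8 else b"       0"

    in_header_ok = len(str(data_end)) <= 8
    header = (
        b"FCS3.1    "
        + hfield(text_begin)
        + hfield(text_end)
        + hfield(data_begin if in_header_ok else 0)
        + hfield(data_end if in_header_ok else 0)
        + hfield(0)
        + hfield(0)
    )
    assert len(header) == HEADER_LEN
    # trailing 8-byte CRC field; "00000000" = not computed
    return header + text + data + b"00000000"


def write_fcs_file(ds: FCSDataset, path: str | Path, **kwargs) -> None:
    Path(path).write_bytes(write_fcs(ds, **kwargs))
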