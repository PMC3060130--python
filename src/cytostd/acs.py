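"""Archival Cytometry Standard (ACS) containers.

An ACS container is a plain ZIP archive (conventionally named ``.acs``)
bundling an experiment's files — raw and preprocessed FCS data, gate
descriptions, classification results — together with an XML table of
contents (ToC) that types each member and records the relations between
them (which file was preprocessed from which, which gating description
applies to which data file, and so on).  Because it is ordinary ZIP, any
stock archive tool can open it.

Dialect pinned here: the ToC lives at the archive root as ``TOC.xml``
(any root member matching ``TOC*.xml`` is accepted on read) under the
namespace in :data:`NS_TOC`.  Integrity is checksum-based: entries carry
optional SHA-256 digests which validation recomputes.  Opaque
``signature`` blocks in the ToC are preserved byte-for-byte on
round-trip as the extension point for real digital signatures.
Relationship terms outside the controlled vocabulary are warnings, not
errors.

Archives are written with zeroed timestamps and a fixed member order so
the same container packs to identical bytes.
"""

from __future__ import annotations

import fnmatch
import hashlib
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

from .errors import FormatError, IntegrityError, ValidationError

__all__ = [
    "TocEntry",
    "TocRelation",
    "Finding",
    "ACSContainer",
    "pack",
    "unpack",
    "validate",
    "toc_to_graph",
    "derived_from",
    "RELATIONSHIP_TERMS",
]

NS_TOC = "http://cytostd.org/acs/toc/v1"
TOC_NAME = "TOC.xml"
TOC_PATTERN = "TOC*.xml"
TOC_VERSION = "1.0"

RELATIONSHIP_TERMS = frozenset(
    {
        "preprocessed-from",
        "gating-description-of",
        "classification-results-of",
        "compensated-version-of",
        "derived-from",
    }
)

#: stored (no deflate) above this member size — decompression speed for
#: very large FCS payloads beats the modest ratio
_STORE_THRESHOLD = 64 * 1024 * 1024


@dataclass
class TocEntry:
    uri: str
    media_type: str
    role: str = ""
    checksum: tuple[str, str] | None = None  # (algorithm, hex digest)


@dataclass
class TocRelation:
    subject_uri: str
    object_uri: str
    relationship: str


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class ACSContainer:
    entries: list[TocEntry] = field(default_factory=list)
    relations: list[TocRelation] = field(default_factory=list)
    members: dict[str, bytes] = field(default_factory=dict)
    version: str | None = TOC_VERSION
    signature_blocks: list[bytes] = field(default_factory=list)

    def add_member(
        self,
        uri: str,
        data: bytes,
        media_type: str,
        role: str = "",
        checksum: bool = True,
    ) -> TocEntry:
        """Add member bytes plus its ToC entry (SHA-256 by default)."""
        if uri in self.members:
            raise ValidationError(f"duplicate member uri {uri!r}")
        self.members[uri] = bytes(data)
        digest = ("SHA-256", hashlib.sha256(data).hexdigest()) if checksum else None
        entry = TocEntry(uri=uri, media_type=media_type, role=role, checksum=digest)
        self.entries.append(entry)
        return entry

    def relate(self, subject_uri: str, relationship: str, object_uri: str) -> None:
        self.relations.append(TocRelation(subject_uri, object_uri, relationship))

    def entry(self, uri: str) -> TocEntry:
        for e in self.entries:
            if e.uri == uri:
                return e
        raise KeyError(uri)


# ---------------------------------------------------------------------------
# ToC XML
# ---------------------------------------------------------------------------

def _q(tag: str) -> str:
    return f"{{{NS_TOC}}}{tag}"


def toc_to_xml(container: ACSContainer) -> bytes:
    attrs = {}
    if container.version is not None:
        attrs["version"] = container.version
    root = etree.Element(_q("tableOfContents"), attrs, nsmap={"toc": NS_TOC})
    for e in container.entries:
        fattrs = {"uri": e.uri, "mediaType": e.media_type}
        if e.role:
            fattrs["role"] = e.role
        fel = etree.SubElement(root, _q("file"), fattrs)
        if e.checksum is not None:
            cel = etree.SubElement(fel, _q("checksum"), {"algorithm": e.checksum[0]})
            cel.text = e.checksum[1]
    for r in container.relations:
        etree.SubElement(
            root, _q("relation"),
            {"subject": r.subject_uri, "relationship": r.relationship,
             "object": r.object_uri},
        )
    for blob in container.signature_blocks:
        sel = etree.SubElement(root, _q("signature"))
        # opaque pass-through: re-embed the preserved XML fragment
        sel.append(etree.fromstring(blob))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def toc_from_xml(data: bytes) -> ACSContainer:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"ToC is not well-formed XML: {exc}") from None
    container = ACSContainer(version=root.get("version"))
    for el in root:
        if not isinstance(el.tag, str):
            continue
        local = etree.QName(el).localname
        if local == "file":
            checksum = None
            for c in el:
                if isinstance(c.tag, str) and etree.QName(c).localname == "checksum":
                    checksum = (c.get("algorithm", "SHA-256"), (c.text or "").strip())
            container.entries.append(
                TocEntry(
                    uri=el.get("uri"), media_type=el.get("mediaType", ""),
                    role=el.get("role", ""), checksum=checksum,
                )
            )
        elif local == "relation":
            container.relations.append(
                TocRelation(
                    subject_uri=el.get("subject"),
                    object_uri=el.get("object"),
                    relationship=el.get("relationship"),
                )
            )
        elif local == "signature":
            for child in el:
                container.signature_blocks.append(etree.tostring(child))
    return container


# ---------------------------------------------------------------------------
# ZIP packing
# ---------------------------------------------------------------------------

def pack(container: ACSContainer) -> bytes:
    """Serialize to ZIP bytes: ToC first, then members in sorted order."""
    uris = set(container.members)
    listed = {e.uri for e in container.entries}
    dangling = sorted(listed - uris)
    if dangling:
        raise IntegrityError(
            "ToC entries without member bytes: " + ", ".join(dangling)
        )
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        def write(name: str, data: bytes) -> None:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = (
                zipfile.ZIP_STORED if len(data) > _STORE_THRESHOLD
                else zipfile.ZIP_DEFLATED
            )
            info.external_attr = 0o644 << 16
            zf.writestr(info, data)

        write(TOC_NAME, toc_to_xml(container))
        for uri in sorted(container.members):
            write(uri, container.members[uri])
    return buf.getvalue()


def unpack(source: bytes | str | Path) -> ACSContainer:
    """Read an ACS container from bytes or a file path."""
    raw = source if isinstance(source, (bytes, bytearray)) else Path(source).read_bytes()
    try:
        zf = zipfile.ZipFile(io.BytesIO(bytes(raw)))
    except zipfile.BadZipFile as exc:
        raise FormatError(f"not a ZIP archive: {exc}") from None
    with zf:
        names = zf.namelist()
        toc_names = [n for n in names if "/" not in n and fnmatch.fnmatch(n, TOC_PATTERN)]
        if not toc_names:
            raise FormatError(
                f"no table of contents ({TOC_PATTERN} at archive root) found"
            )
        container = toc_from_xml(zf.read(toc_names[0]))
        for name in names:
            if name in toc_names or name.endswith("/"):
                continue
            container.members[name] = zf.read(name)
    return container


def containers_equal(a: ACSContainer, b: ACSContainer) -> bool:
    return (
        a.entries == b.entries
        and a.relations == b.relations
        and a.members == b.members
        and a.version == b.version
        and a.signature_blocks == b.signature_blocks
    )


# ---------------------------------------------------------------------------
# Validation and the relation graph
# ---------------------------------------------------------------------------

def validate(container: ACSContainer) -> list[Finding]:
    """Consistency report: an empty list means a fully consistent container.

    Errors: ToC entries without members (DANGLING_ENTRY), checksum
    mismatches (CHECKSUM_MISMATCH), relations naming unlisted uris
    (DANGLING_RELATION), duplicate uris (DUPLICATE_URI).  Warnings:
    members not listed in the ToC (ORPHAN_MEMBER), relationship terms
    outside the controlled vocabulary (UNKNOWN_RELATIONSHIP), a missing
    ToC version (MISSING_VERSION).
    """
    findings: list[Finding] = []
    listed = [e.uri for e in container.entries]
    seen: set[str] = set()
    for uri in listed:
        if uri in seen:
            findings.append(
                Finding("error", "DUPLICATE_URI", f"uri listed twice in ToC: {uri}")
            )
        seen.add(uri)
    for e in container.entries:
        if e.uri not in container.members:
            findings.append(
                Finding("error", "DANGLING_ENTRY",
                        f"ToC lists {e.uri} but the archive has no such member")
            )
        elif e.checksum is not None:
            algo, expected = e.checksum
            try:
                h = hashlib.new(algo.replace("-", "").lower())
            except ValueError:
                findings.append(
                    Finding("warning", "UNKNOWN_CHECKSUM_ALGORITHM",
                            f"{e.uri}: unknown algorithm {algo!r}")
                )
                continue
            h.update(container.members[e.uri])
            actual = h.hexdigest()
            if actual != expected.lower():
                findings.append(
                    Finding("error", "CHECKSUM_MISMATCH",
                            f"{e.uri}: expected {algo} {expected}, got {actual}")
                )
    for uri in container.members:
        if uri not in seen:
            findings.append(
                Finding("warning", "ORPHAN_MEMBER",
                        f"member {uri} is not listed in the ToC")
            )
    for r in container.relations:
        for uri in (r.subject_uri, r.object_uri):
            if uri not in seen:
                findings.append(
                    Finding("error", "DANGLING_RELATION",
                            f"relation {r.relationship!r} references unlisted uri {uri}")
                )
        if r.relationship not in RELATIONSHIP_TERMS:
            findings.append(
                Finding("warning", "UNKNOWN_RELATIONSHIP",
                        f"relationship term {r.relationship!r} is not in the "
                        "controlled vocabulary")
            )
    if container.version is None:
        findings.append(
            Finding("warning", "MISSING_VERSION", "ToC has no version attribute")
        )
    return findings


def toc_to_graph(container: ACSContainer) -> nx.DiGraph:
    """Directed graph: nodes = ToC entries, edge subject -> object per relation."""
    g = nx.DiGraph()
    for e in container.entries:
        g.add_node(e.uri, media_type=e.media_type, role=e.role)
    for r in container.relations:
        g.add_edge(r.subject_uri, r.object_uri, relationship=r.relationship)
    return g


def derived_from(container: ACSContainer, uri: str) -> set[str]:
    """All files whose relation chain leads to ``uri`` (transitive closure)."""
    g = toc_to_graph(container)
    if uri not in g:
        raise KeyError(uri)
    return set(nx.ancestors(g, uri))
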