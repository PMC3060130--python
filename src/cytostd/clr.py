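"""Classification Results (CLR) tables: fuzzy per-event class membership.

A CLR table stores, for every event of a source FCS file, the
probability of that event belonging to each of m classes — the output of
manual or automated gating.  The on-disk form is plain CSV (RFC 4180
quoting) so any spreadsheet can open it: one header row of class labels,
then one row per event in the source file's event order.  An optional
leading comment line ``#source=<name>`` records which FCS file the rows
index.  Values are serialized with ``repr`` (shortest round-tripping
form, up to 17 significant digits), so read(write(t)) is exact.

Row sums may exceed 1 when classes overlap; ``strict`` validation
(row sums <= 1 + 1e-9) is opt-in because fuzzy, overlapping classes are
legal.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "CLRTable",
    "read_clr",
    "write_clr",
    "hard_assignment",
    "clr_from_memberships",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"
_ROW_SUM_TOL = 1e-9


@dataclass
class CLRTable:
    """Ordered class labels plus an (n_events, m) probability matrix."""

    class_labels: list[str]
    memberships: np.ndarray
    source_ref: str | None = None

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=np.float64)
        if self.memberships.ndim != 2:
            raise ValidationError("membership matrix must be 2-D")
        m = len(self.class_labels)
        if self.memberships.shape[1] != m:
            raise ValidationError(
                f"{self.memberships.shape[1]} columns but {m} class labels"
            )
        if m == 0:
            raise ValidationError("CLR table needs at least one class")
        if any(not lbl for lbl in self.class_labels):
            raise ValidationError("class labels must be non-empty")
        if len(set(self.class_labels)) != m:
            raise ValidationError("class labels must be unique")

    @property
    def n_events(self) -> int:
        return self.memberships.shape[0]

    @property
    def n_classes(self) -> int:
        return self.memberships.shape[1]

    def validate(self, strict: bool = False) -> None:
        """Check the [0, 1] bound per value; ``strict`` also bounds row sums."""
        bad = ~((self.memberships >= 0.0) & (self.memberships <= 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"({r}, {c}): {float(self.memberships[r, c])!r} ∉ [0,1]"
            )
        if strict:
            sums = self.memberships.sum(axis=1)
            over = sums > 1.0 + _ROW_SUM_TOL
            if over.any():
                r = int(np.argmax(over))
                raise ValidationError(
                    f"strict mode: row {r} memberships sum to {float(sums[r])!r} > 1"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CLRTable)
            and self.class_labels == other.class_labels
            and self.source_ref == other.source_ref
            and np.array_equal(self.memberships, other.memberships)
        )


def write_clr(table: CLRTable, strict: bool = False) -> str:
    """Serialize to CSV text (CRLF line endings per RFC 4180)."""
    table.validate(strict=strict)
    buf = io.StringIO()
    if table.source_ref is not None:
        buf.write(f"#source={table.source_ref}\r\n")
    w = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    w.writerow(table.class_labels)
    for row in table.memberships:
        w.writerow([repr(float(v)) for v in row])
    return buf.getvalue()


def read_clr(source, strict: bool = False) -> CLRTable:
    """Parse CLR CSV text (or a file path) into a validated table."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    source_ref = None
    if text.startswith("#source="):
        first, _, rest = text.partition("\n")
        source_ref = first[len("#source="):].rstrip("\r")
        text = rest
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if r]  # tolerate trailing blank lines
    if not rows:
        raise FormatError("CLR file has no header row")
    labels = rows[0]
    m = len(labels)
    data = np.empty((len(rows) - 1, m), dtype=np.float64)
    for i, row in enumerate(rows[1:]):
        if len(row) != m:
            raise FormatError(
                f"ragged CLR row {i + 1}: {len(row)} fields, expected {m}"
            )
        try:
            data[i] = [float(v) for v in row]
        except ValueError as exc:
            raise FormatError(f"non-numeric value in CLR row {i + 1}: {exc}") from None
    table = CLRTable(class_labels=labels, memberships=data, source_ref=source_ref)
    table.validate(strict=strict)
    return table


def hard_assignment(
    table: CLRTable, threshold: float = 0.5, tie_rule: str = "first-label"
) -> np.ndarray:
    """Per-event argmax label, or ``unclassified`` below ``threshold``.

    Ties are broken by ``first-label`` (the earliest class in label
    order) or mapped to ``unclassified`` with ``tie_rule="unclassified"``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} ∉ [0,1]")
    if tie_rule not in ("first-label", "unclassified"):
        raise ValidationError(f"unknown tie rule {tie_rule!r}")
    p = table.memberships
    best = np.argmax(p, axis=1)  # first max wins
    top = p[np.arange(p.shape[0]), best]
    labels = np.asarray(table.class_labels, dtype=object)
    out = np.where(top >= threshold, labels[best], UNCLASSIFIED)
    if tie_rule == "unclassified":
        tied = (p == top[:, None]).sum(axis=1) > 1
        out = np.where(tied & (top >= threshold), UNCLASSIFIED, out)
    return out.astype(object)


def clr_from_memberships(
    memberships, labels: list[str], source_ref: str | None = None,
    strict: bool = False,
) -> CLRTable:
    """Build a 0/1 CLR table from boolean gate-membership vectors.

    ``memberships`` is a sequence of equal-length boolean vectors, one
    per label — this is how manual gating results are put into CLR form.
    """
    vecs = [np.asarray(v, dtype=bool) for v in memberships]
    if len(vecs) != len(labels):
        raise ValidationError(
            f"{len(vecs)} membership vectors but {len(labels)} labels"
        )
    if len({v.shape[0] for v in vecs}) > 1:
        raise ValidationError("membership vectors differ in length")
    table = CLRTable(
        class_labels=list(labels),
        memberships=np.column_stack(vecs).astype(np.float64),
        source_ref=source_ref,
    )
    table.validate(strict=strict)
    return table
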