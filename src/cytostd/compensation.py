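"""Spillover matrices and fluorescence compensation.

A spillover matrix S records detector crosstalk: S[i, j] is the fraction
of fluorochrome i's signal that appears in detector j.  With events as
row vectors, observed = true @ S, so compensation multiplies observed
values by S^-1 on the right.  This orientation matches the FCS 3.1
$SPILLOVER keyword (rows = fluorochromes, columns = detectors); vendor
tools disagree on it, so it is fixed and documented here.

Matrices parsed with non-unit diagonals are normalized by their diagonal
(with a warning), as the keyword permits scaled representations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, MappingError, NumericalError, ValidationError

__all__ = [
    "SpilloverMatrix",
    "parse_spillover_keyword",
    "serialize_spillover_keyword",
    "apply_spillover",
    "compensate",
]


@dataclass
class SpilloverMatrix:
    """k detector names plus the k x k crosstalk matrix S (diagonal 1)."""

    detectors: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        k = len(self.detectors)
        if k < 1:
            raise ValidationError("spillover matrix needs at least one detector")
        if self.S.shape != (k, k):
            raise ValidationError(
                f"spillover matrix shape {self.S.shape} does not match "
                f"{k} detectors"
            )
        if len(set(self.detectors)) != k:
            raise ValidationError("duplicate detector names in spillover matrix")
        diag = np.diag(self.S)
        if not np.allclose(diag, 1.0, rtol=0, atol=1e-12):
            if (diag == 0).any():
                raise ValidationError("spillover matrix has a zero diagonal entry")
            warnings.warn(
                "spillover matrix diagonal is not 1; normalizing rows by the "
                "diagonal", stacklevel=2,
            )
            self.S = self.S / diag[:, None]

    @property
    def k(self) -> int:
        return len(self.detectors)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.S))

    def inverse(self) -> np.ndarray:
        scale = float(np.abs(self.S).max())
        if abs(np.linalg.det(self.S)) < 1e-12 * scale**self.k:
            raise NumericalError(
                "spillover matrix is singular or nearly so "
                f"(cond={self.condition_number:.3g}); inspect the matrix"
            )
        return np.linalg.inv(self.S)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpilloverMatrix)
            and self.detectors == other.detectors
            and np.array_equal(self.S, other.S)
        )


def parse_spillover_keyword(value: str) -> SpilloverMatrix:
    """Parse an FCS 3.1 $SPILLOVER value: "k,name1,...,namek,v11,...,vkk"."""
    tokens = [t.strip() for t in value.split(",")]
    try:
        k = int(tokens[0])
    except ValueError:
        raise FormatError(
            f"$SPILLOVER must start with an integer count, got {tokens[0]!r}"
        ) from None
    expected = 1 + k + k * k
    if len(tokens) != expected:
        raise FormatError(
            f"$SPILLOVER with k={k} needs {expected} tokens, got {len(tokens)}"
        )
    names = tokens[1 : 1 + k]
    vals = np.empty(k * k, dtype=np.float64)
    for i, tok in enumerate(tokens[1 + k :]):
        try:
            vals[i] = float(tok)
        except ValueError:
            raise FormatError(
                f"non-numeric $SPILLOVER matrix entry {tok!r} at token "
                f"{1 + k + i}"
            ) from None
    return SpilloverMatrix(detectors=names, S=vals.reshape(k, k))


def serialize_spillover_keyword(spill: SpilloverMatrix) -> str:
    """Emit the $SPILLOVER keyword value (row-major, full precision)."""
    parts = [str(spill.k)] + list(spill.detectors)
    parts += [repr(float(v)) for v in spill.S.ravel()]
    return ",".join(parts)


def _column_indices(spill: SpilloverMatrix, channel_map) -> np.ndarray:
    """Resolve detector names to event-matrix column indices."""
    if channel_map is None:
        raise MappingError("a detector -> column mapping is required")
    if hasattr(channel_map, "channel_index"):  # an FCSDataset
        lookup = {n: i for i, n in enumerate(channel_map.channel_names)}
    elif isinstance(channel_map, dict):
        lookup = channel_map
    else:  # a sequence of column names
        lookup = {n: i for i, n in enumerate(channel_map)}
    idx = []
    for name in spill.detectors:
        if name not in lookup:
            raise MappingError(
                f"spillover detector {name!r} matches no event column; "
                f"candidates: {', '.join(map(str, lookup))}"
            )
        idx.append(lookup[name])
    if len(set(idx)) != len(idx):
        raise MappingError("spillover detectors map to non-distinct columns")
    return np.asarray(idx)


def apply_spillover(events: np.ndarray, spill: SpilloverMatrix, channel_map) -> np.ndarray:
    """Simulate crosstalk: replace mapped columns by true @ S."""
    idx = _column_indices(spill, channel_map)
    out = np.array(events, dtype=np.float64, copy=True)
    out[:, idx] = out[:, idx] @ spill.S
    return out


def compensate(events: np.ndarray, spill: SpilloverMatrix, channel_map) -> np.ndarray:
    """Undo crosstalk: replace mapped columns by observed @ S^-1.

    Unmapped columns (scatter, time) are returned untouched.
    """
    idx = _column_indices(spill, channel_map)
    inv = spill.inverse()
    out = np.array(events, dtype=np.float64, copy=True)
    out[:, idx] = out[:, idx] @ inv
    return out
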