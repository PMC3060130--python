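"""Gate descriptions: data model, XML serialization, and evaluation.

Gating is the selection of cell subpopulations by geometric regions over
one or more channels.  This module models rectangle, polygon, ellipsoid
and Boolean gates arranged in a parent-child hierarchy (a child selects
within its parent's population), reads and writes them as Gating-ML
style XML, and evaluates them against an :class:`~cytostd.fcs.FCSDataset`
as vectorized membership tests.

Evaluation semantics
--------------------
Per dimension, events are first compensated (``uncompensated``, the
file's own $SPILLOVER via ``FCS``, or an explicit spectrum-matrix id)
and then mapped through the referenced display transform.  Boundary
rules are pinned: rectangles are min-edge inclusive / max-edge
exclusive; polygon and ellipsoid boundaries are inclusive.  Polygon
membership uses crossing-number (even-odd) semantics, so
self-intersecting polygons are legal.  Rectangles are evaluated in data
space by inverse-transforming their bounds (the transforms are strictly
increasing, so order is preserved); polygons and ellipsoids are
evaluated in display space.

Quadrant gates, decision trees and curly quadrants are recognized but
deliberately unsupported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .compensation import SpilloverMatrix, compensate, parse_spillover_keyword
from .errors import (
    ChannelError,
    FormatError,
    GateReferenceError,
    UnsupportedFeatureError,
    ValidationError,
)
from .fcs import FCSDataset
from .transforms import Transform, apply_transform, invert_transform

__all__ = [
    "Dimension",
    "RectangleGate",
    "PolygonGate",
    "EllipsoidGate",
    "BooleanGate",
    "GatingStrategy",
    "read_gatingml",
    "write_gatingml",
    "evaluate_gate",
    "evaluate_all",
    "points_in_polygon",
]

NS_GATING = "http://www.isac-net.org/std/Gating-ML/v2.0/gating"
NS_TRANSFORMS = "http://www.isac-net.org/std/Gating-ML/v2.0/transformations"
NS_DATATYPES = "http://www.isac-net.org/std/Gating-ML/v2.0/datatypes"
#: namespaces accepted on read where the element shapes coincide
ACCEPTED_GATING_NAMESPACES = (
    NS_GATING,
    "http://www.isac-net.org/std/Gating-ML/v1.5/gating",
)

#: compensation-ref sentinel values
UNCOMPENSATED = "uncompensated"
FCS_SPILLOVER = "FCS"

_UNSUPPORTED_GATES = ("QuadrantGate", "DecisionTreeGate", "CurlyQuadrantGate")


@dataclass(frozen=True)
class Dimension:
    channel_name: str
    transform_ref: str | None = None
    compensation_ref: str = UNCOMPENSATED
    min: float = -math.inf
    max: float = math.inf

    def __post_init__(self) -> None:
        if self.min >= self.max:
            raise ValidationError(
                f"dimension {self.channel_name}: min {self.min} must be "
                f"< max {self.max}"
            )


@dataclass
class RectangleGate:
    id: str
    dims: list[Dimension]
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.dims:
            raise ValidationError(f"gate {self.id}: needs at least one dimension")


@dataclass
class PolygonGate:
    id: str
    dims: list[Dimension]  # exactly two
    vertices: list[tuple[float, float]]
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.dims) != 2:
            raise ValidationError(f"gate {self.id}: polygon needs 2 dimensions")
        if len(self.vertices) < 3:
            raise ValidationError(f"gate {self.id}: polygon needs >= 3 vertices")
        v = np.asarray(self.vertices, dtype=np.float64)
        x, y = v[:, 0], v[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area2 == 0.0:
            raise ValidationError(f"gate {self.id}: polygon has zero area")


@dataclass
class EllipsoidGate:
    id: str
    dims: list[Dimension]
    mean: np.ndarray
    covariance: np.ndarray
    distance_square: float
    parent_id: str | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        d = len(self.dims)
        if self.mean.shape != (d,) or self.covariance.shape != (d, d):
            raise ValidationError(f"gate {self.id}: mean/covariance shape mismatch")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValidationError(f"gate {self.id}: covariance not symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValidationError(f"gate {self.id}: covariance not positive definite")
        if self.distance_square <= 0:
            raise ValidationError(f"gate {self.id}: distance_square must be > 0")


@dataclass(frozen=True)
class GateReference:
    ref: str
    complement: bool = False


@dataclass
class BooleanGate:
    id: str
    operator: str  # AND | OR | NOT
    operands: list[GateReference]
    parent_id: str | None = None

    def __post_init__(self) -> None:
        op = self.operator.upper()
        if op not in ("AND", "OR", "NOT"):
            raise ValidationError(f"gate {self.id}: unknown operator {self.operator!r}")
        self.operator = op
        if op == "NOT" and len(self.operands) != 1:
            raise ValidationError(f"gate {self.id}: NOT takes exactly one operand")
        if op in ("AND", "OR") and len(self.operands) < 2:
            raise ValidationError(f"gate {self.id}: {op} needs >= 2 operands")


Gate = RectangleGate | PolygonGate | EllipsoidGate | BooleanGate


@dataclass
class GatingStrategy:
    """Named gates plus the transforms and spectrum matrices they reference."""

    gates: dict[str, Gate] = field(default_factory=dict)
    transforms: dict[str, Transform] = field(default_factory=dict)
    spectrum_matrices: dict[str, SpilloverMatrix] = field(default_factory=dict)

    def add_gate(self, gate: Gate) -> "GatingStrategy":
        if gate.id in self.gates or gate.id in self.transforms or gate.id in self.spectrum_matrices:
            raise ValidationError(f"duplicate id {gate.id!r}")
        self.gates[gate.id] = gate
        return self

    def add_transform(self, t: Transform) -> "GatingStrategy":
        if t.id in self.gates or t.id in self.transforms or t.id in self.spectrum_matrices:
            raise ValidationError(f"duplicate id {t.id!r}")
        self.transforms[t.id] = t
        return self

    def add_spectrum_matrix(self, mid: str, spill: SpilloverMatrix) -> "GatingStrategy":
        if mid in self.gates or mid in self.transforms or mid in self.spectrum_matrices:
            raise ValidationError(f"duplicate id {mid!r}")
        self.spectrum_matrices[mid] = spill
        return self

    def validate(self) -> None:
        """Check reference resolution and hierarchy acyclicity."""
        missing = []
        for g in self.gates.values():
            if g.parent_id is not None and g.parent_id not in self.gates:
                missing.append(g.parent_id)
            if isinstance(g, BooleanGate):
                missing += [r.ref for r in g.operands if r.ref not in self.gates]
            else:
                for d in g.dims:
                    if d.transform_ref and d.transform_ref not in self.transforms:
                        missing.append(d.transform_ref)
                    if d.compensation_ref not in (UNCOMPENSATED, FCS_SPILLOVER) and \
                            d.compensation_ref not in self.spectrum_matrices:
                        missing.append(d.compensation_ref)
        if missing:
            raise GateReferenceError(
                "unresolved references: " + ", ".join(sorted(set(missing)))
            )
        for gid in self.gates:
            self._check_acyclic(gid, [])

    def _check_acyclic(self, gid: str, path: list[str]) -> None:
        if gid in path:
            cycle = path[path.index(gid):] + [gid]
            raise GateReferenceError("reference cycle: " + " -> ".join(cycle))
        g = self.gates[gid]
        nxt = []
        if g.parent_id is not None:
            nxt.append(g.parent_id)
        if isinstance(g, BooleanGate):
            nxt += [r.ref for r in g.operands]
        for n in nxt:
            if n in self.gates:
                self._check_acyclic(n, path + [gid])

    def children(self, gate_id: str | None) -> list[str]:
        return [g.id for g in self.gates.values() if g.parent_id == gate_id]


# ---------------------------------------------------------------------------
# Geometry kernels
# ---------------------------------------------------------------------------

def points_in_polygon(px: np.ndarray, py: np.ndarray, vertices) -> np.ndarray:
    """Vectorized even-odd (crossing number) test, boundary inclusive."""
    v = np.asarray(vertices, dtype=np.float64)
    px = np.asarray(px, dtype=np.float64)
    py = np.asarray(py, dtype=np.float64)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # edge crossing of the rightward horizontal ray from each point
        cond = (y1 <= py) != (y2 <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < xint)
        # boundary: point within the segment's bounding box and collinear
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        scale = max(abs(x2 - x1), abs(y2 - y1), 1.0)
        near = np.abs(cross) <= 1e-12 * scale * np.maximum(
            np.maximum(np.abs(px), np.abs(py)), 1.0
        )
        inbox = (
            (px >= min(x1, x2)) & (px <= max(x1, x2))
            & (py >= min(y1, y2)) & (py <= max(y1, y2))
        )
        on_edge |= near & inbox
    return inside | on_edge


def _mahalanobis_sq(pts: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = pts - mean
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class _EvalContext:
    """Caches compensated matrices and gate memberships per evaluation run."""

    def __init__(self, strategy: GatingStrategy, dataset: FCSDataset):
        self.strategy = strategy
        self.dataset = dataset
        self._comp_cache: dict[str, np.ndarray] = {}
        self.membership: dict[str, np.ndarray] = {}
        self._in_progress: list[str] = []

    def compensated(self, ref: str) -> np.ndarray:
        if ref in self._comp_cache:
            return self._comp_cache[ref]
        ds = self.dataset
        if ref == UNCOMPENSATED:
            mat = ds.events
        elif ref == FCS_SPILLOVER:
            if "$SPILLOVER" not in ds.keywords:
                raise GateReferenceError(
                    "gate requests the file's spillover but the dataset has "
                    "no $SPILLOVER keyword"
                )
            spill = parse_spillover_keyword(ds.keywords["$SPILLOVER"])
            mat = compensate(ds.events, spill, ds)
        else:
            spill = self.strategy.spectrum_matrices.get(ref)
            if spill is None:
                raise GateReferenceError(f"unknown spectrum matrix id {ref!r}")
            mat = compensate(ds.events, spill, ds)
        self._comp_cache[ref] = mat
        return mat

    def dim_data(self, dim: Dimension) -> np.ndarray:
        """Compensated data-space values for one dimension."""
        col = self.dataset.channel_index(dim.channel_name)
        return self.compensated(dim.compensation_ref)[:, col]

    def dim_display(self, dim: Dimension) -> np.ndarray:
        """Compensated then transformed values for one dimension."""
        x = self.dim_data(dim)
        if dim.transform_ref:
            t = self.strategy.transforms.get(dim.transform_ref)
            if t is None:
                raise GateReferenceError(f"unknown transform id {dim.transform_ref!r}")
            return apply_transform(t, x)
        return x


def _own_membership(
    gate: Gate, ctx: _EvalContext, rectangle_space: str = "data"
) -> np.ndarray:
    """The gate's geometric predicate, ignoring its parent."""
    strategy = ctx.strategy
    if isinstance(gate, RectangleGate):
        keep = np.ones(ctx.dataset.n_events, dtype=bool)
        for dim in gate.dims:
            if rectangle_space == "data" or dim.transform_ref is None:
                x = ctx.dim_data(dim)
                lo, hi = dim.min, dim.max
                if dim.transform_ref is not None:
                    t = strategy.transforms[dim.transform_ref]
                    if math.isfinite(lo):
                        lo = float(invert_transform(t, lo))
                    if math.isfinite(hi):
                        hi = float(invert_transform(t, hi))
            else:
                x = ctx.dim_display(dim)
                lo, hi = dim.min, dim.max
            keep &= (x >= lo) & (x < hi)
        return keep
    if isinstance(gate, PolygonGate):
        px = ctx.dim_display(gate.dims[0])
        py = ctx.dim_display(gate.dims[1])
        return points_in_polygon(px, py, gate.vertices)
    if isinstance(gate, EllipsoidGate):
        pts = np.column_stack([ctx.dim_display(d) for d in gate.dims])
        d2 = _mahalanobis_sq(pts, gate.mean, gate.covariance)
        return d2 <= gate.distance_square
    if isinstance(gate, BooleanGate):
        parts = []
        for ref in gate.operands:
            m = _membership(ref.ref, ctx)
            parts.append(~m if ref.complement else m)
        if gate.operator == "NOT":
            return ~parts[0]
        if gate.operator == "AND":
            return np.logical_and.reduce(parts)
        return np.logical_or.reduce(parts)
    raise UnsupportedFeatureError(f"unsupported gate type {type(gate).__name__}")


def _membership(gate_id: str, ctx: _EvalContext) -> np.ndarray:
    if gate_id in ctx.membership:
        return ctx.membership[gate_id]
    if gate_id in ctx._in_progress:
        cycle = ctx._in_progress[ctx._in_progress.index(gate_id):] + [gate_id]
        raise GateReferenceError("reference cycle: " + " -> ".join(cycle))
    gate = ctx.strategy.gates.get(gate_id)
    if gate is None:
        raise GateReferenceError(f"unknown gate id {gate_id!r}")
    ctx._in_progress.append(gate_id)
    try:
        m = _own_membership(gate, ctx)
        if gate.parent_id is not None:
            m = m & _membership(gate.parent_id, ctx)
    finally:
        ctx._in_progress.pop()
    ctx.membership[gate_id] = m
    return m


def evaluate_gate(
    strategy: GatingStrategy, gate_id: str, dataset: FCSDataset
) -> np.ndarray:
    """Boolean membership vector (length n_events) for one gate.

    Membership is the gate's own geometric predicate AND-ed with its
    parent's membership, recursively.
    """
    ctx = _EvalContext(strategy, dataset)
    return _membership(gate_id, ctx)


def evaluate_all(strategy: GatingStrategy, dataset: FCSDataset):
    """Evaluate every gate; returns (memberships, statistics).

    ``memberships`` maps gate id to a boolean vector; ``statistics`` maps
    gate id to a dict with ``count``, ``pct_of_parent`` and
    ``pct_of_total`` (percentages, 0-100; an empty parent yields 0).
    """
    strategy.validate()
    ctx = _EvalContext(strategy, dataset)
    for gid in strategy.gates:
        _membership(gid, ctx)
    n = dataset.n_events
    stats: dict[str, dict] = {}
    for gid, gate in strategy.gates.items():
        count = int(ctx.membership[gid].sum())
        if gate.parent_id is None:
            parent_n = n
        else:
            parent_n = int(ctx.membership[gate.parent_id].sum())
        stats[gid] = {
            "count": count,
            "parent": gate.parent_id,
            "pct_of_parent": 100.0 * count / parent_n if parent_n else 0.0,
            "pct_of_total": 100.0 * count / n if n else 0.0,
        }
    return ctx.membership, stats


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------

_NSMAP = {"gating": NS_GATING, "transforms": NS_TRANSFORMS, "data-type": NS_DATATYPES}


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _fmt(v: float) -> str:
    return repr(float(v))


def _write_dimension(parent, dim: Dimension, with_bounds: bool) -> None:
    attrs = {_q(NS_GATING, "compensation-ref"): dim.compensation_ref}
    if dim.transform_ref:
        attrs[_q(NS_GATING, "transformation-ref")] = dim.transform_ref
    if with_bounds:
        if math.isfinite(dim.min):
            attrs[_q(NS_GATING, "min")] = _fmt(dim.min)
        if math.isfinite(dim.max):
            attrs[_q(NS_GATING, "max")] = _fmt(dim.max)
    el = etree.SubElement(parent, _q(NS_GATING, "dimension"), attrs)
    etree.SubElement(
        el, _q(NS_DATATYPES, "fcs-dimension"),
        {_q(NS_DATATYPES, "name"): dim.channel_name},
    )


def write_gatingml(strategy: GatingStrategy) -> bytes:
    """Serialize a strategy to Gating-ML style XML (UTF-8 bytes)."""
    strategy.validate()
    root = etree.Element(_q(NS_GATING, "Gating-ML"), nsmap=_NSMAP)
    for t in strategy.transforms.values():
        tel = etree.SubElement(
            root, _q(NS_TRANSFORMS, "transformation"),
            {_q(NS_TRANSFORMS, "id"): t.id},
        )
        attrs = {_q(NS_TRANSFORMS, "T"): _fmt(t.T)}
        if t.kind != "flin":
            attrs[_q(NS_TRANSFORMS, "M")] = _fmt(t.M)
        if t.kind in ("logicle", "hyperlog"):
            attrs[_q(NS_TRANSFORMS, "W")] = _fmt(t.W)
        if t.kind != "flog":
            attrs[_q(NS_TRANSFORMS, "A")] = _fmt(t.A)
        etree.SubElement(tel, _q(NS_TRANSFORMS, t.kind), attrs)
    for mid, spill in strategy.spectrum_matrices.items():
        mel = etree.SubElement(
            root, _q(NS_TRANSFORMS, "spectrumMatrix"),
            {_q(NS_TRANSFORMS, "id"): mid},
        )
        det = etree.SubElement(mel, _q(NS_TRANSFORMS, "detectors"))
        for name in spill.detectors:
            etree.SubElement(
                det, _q(NS_DATATYPES, "fcs-dimension"),
                {_q(NS_DATATYPES, "name"): name},
            )
        for row in spill.S:
            rel = etree.SubElement(mel, _q(NS_TRANSFORMS, "spectrum"))
            for v in row:
                etree.SubElement(
                    rel, _q(NS_TRANSFORMS, "coefficient"),
                    {_q(NS_TRANSFORMS, "value"): _fmt(v)},
                )
    for gate in strategy.gates.values():
        gattrs = {_q(NS_GATING, "id"): gate.id}
        if gate.parent_id is not None:
            gattrs[_q(NS_GATING, "parent_id")] = gate.parent_id
        if isinstance(gate, RectangleGate):
            gel = etree.SubElement(root, _q(NS_GATING, "RectangleGate"), gattrs)
            for dim in gate.dims:
                _write_dimension(gel, dim, with_bounds=True)
        elif isinstance(gate, PolygonGate):
            gel = etree.SubElement(root, _q(NS_GATING, "PolygonGate"), gattrs)
            for dim in gate.dims:
                _write_dimension(gel, dim, with_bounds=False)
            for x, y in gate.vertices:
                vel = etree.SubElement(gel, _q(NS_GATING, "vertex"))
                etree.SubElement(
                    vel, _q(NS_GATING, "coordinate"), {_q(NS_DATATYPES, "value"): _fmt(x)}
                )
                etree.SubElement(
                    vel, _q(NS_GATING, "coordinate"), {_q(NS_DATATYPES, "value"): _fmt(y)}
                )
        elif isinstance(gate, EllipsoidGate):
            gel = etree.SubElement(root, _q(NS_GATING, "EllipsoidGate"), gattrs)
            for dim in gate.dims:
                _write_dimension(gel, dim, with_bounds=False)
            mel = etree.SubElement(gel, _q(NS_GATING, "mean"))
            for v in gate.mean:
                etree.SubElement(
                    mel, _q(NS_GATING, "coordinate"), {_q(NS_DATATYPES, "value"): _fmt(v)}
                )
            cel = etree.SubElement(gel, _q(NS_GATING, "covarianceMatrix"))
            for row in gate.covariance:
                rel = etree.SubElement(cel, _q(NS_GATING, "row"))
                for v in row:
                    etree.SubElement(
                        rel, _q(NS_GATING, "entry"), {_q(NS_DATATYPES, "value"): _fmt(v)}
                    )
            etree.SubElement(
                gel, _q(NS_GATING, "distanceSquare"),
                {_q(NS_DATATYPES, "value"): _fmt(gate.distance_square)},
            )
        elif isinstance(gate, BooleanGate):
            gel = etree.SubElement(root, _q(NS_GATING, "BooleanGate"), gattrs)
            oel = etree.SubElement(gel, _q(NS_GATING, gate.operator.lower()))
            for ref in gate.operands:
                rattrs = {_q(NS_GATING, "ref"): ref.ref}
                if ref.complement:
                    rattrs[_q(NS_GATING, "use-as-complement")] = "true"
                etree.SubElement(oel, _q(NS_GATING, "gateReference"), rattrs)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _local(el) -> str:
    return etree.QName(el).localname


def _attr(el, name: str) -> str | None:
    """Namespace-tolerant attribute lookup (qualified or bare)."""
    for key, val in el.attrib.items():
        if key == name or key.endswith("}" + name):
            return val
    return None


def _read_dimension(el) -> Dimension:
    fcs_dim = next(
        (c for c in el if isinstance(c.tag, str) and _local(c) == "fcs-dimension"), None
    )
    if fcs_dim is None:
        raise FormatError("dimension element lacks an fcs-dimension child")
    name = _attr(fcs_dim, "name")
    lo = _attr(el, "min")
    hi = _attr(el, "max")
    return Dimension(
        channel_name=name,
        transform_ref=_attr(el, "transformation-ref"),
        compensation_ref=_attr(el, "compensation-ref") or UNCOMPENSATED,
        min=float(lo) if lo is not None else -math.inf,
        max=float(hi) if hi is not None else math.inf,
    )


_TRANSFORM_KINDS = {"flin", "flog", "fasinh", "logicle", "hyperlog"}


def _read_transform(el) -> Transform:
    tid = _attr(el, "id")
    kind_el = next(
        (c for c in el if isinstance(c.tag, str) and _local(c) in _TRANSFORM_KINDS),
        None,
    )
    if kind_el is None:
        names = [_local(c) for c in el if isinstance(c.tag, str)]
        raise UnsupportedFeatureError(
            f"transformation {tid!r}: unsupported function {names}"
        )
    kind = _local(kind_el)
    kw = {}
    for p in ("T", "M", "W", "A"):
        v = _attr(kind_el, p)
        if v is not None:
            kw[p] = float(v)
    return Transform(id=tid, kind=kind, **kw)


def _read_spectrum_matrix(el) -> tuple[str, SpilloverMatrix]:
    mid = _attr(el, "id")
    names: list[str] = []
    rows: list[list[float]] = []
    for c in el:
        if not isinstance(c.tag, str):
            continue
        if _local(c) == "detectors":
            names = [_attr(d, "name") for d in c if isinstance(d.tag, str)]
        elif _local(c) == "spectrum":
            rows.append(
                [float(_attr(v, "value")) for v in c if isinstance(v.tag, str)]
            )
    return mid, SpilloverMatrix(detectors=names, S=np.asarray(rows))


def read_gatingml(source) -> GatingStrategy:
    """Parse Gating-ML style XML (bytes, text, or a file path)."""
    if isinstance(source, (bytes, bytearray)):
        root = etree.fromstring(bytes(source))
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode("utf-8"))
    else:
        root = etree.parse(str(source)).getroot()
    ns = etree.QName(root).namespace
    if ns not in ACCEPTED_GATING_NAMESPACES:
        raise FormatError(
            f"unrecognized Gating-ML namespace {ns!r}; accepted: "
            f"{', '.join(ACCEPTED_GATING_NAMESPACES)}"
        )
    strategy = GatingStrategy()
    for el in root:
        if not isinstance(el.tag, str):
            continue
        local = _local(el)
        gid = _attr(el, "id")
        parent = _attr(el, "parent_id")
        if local in _UNSUPPORTED_GATES:
            raise UnsupportedFeatureError(f"gate element {local!r} is not supported")
        if local == "transformation":
            strategy.add_transform(_read_transform(el))
        elif local == "spectrumMatrix":
            mid, spill = _read_spectrum_matrix(el)
            strategy.add_spectrum_matrix(mid, spill)
        elif local == "RectangleGate":
            dims = [_read_dimension(c) for c in el
                    if isinstance(c.tag, str) and _local(c) == "dimension"]
            strategy.add_gate(RectangleGate(id=gid, parent_id=parent, dims=dims))
        elif local == "PolygonGate":
            dims, verts = [], []
            for c in el:
                if not isinstance(c.tag, str):
                    continue
                if _local(c) == "dimension":
                    dims.append(_read_dimension(c))
                elif _local(c) == "vertex":
                    coords = [float(_attr(v, "value")) for v in c
                              if isinstance(v.tag, str)]
                    verts.append((coords[0], coords[1]))
            strategy.add_gate(
                PolygonGate(id=gid, parent_id=parent, dims=dims, vertices=verts)
            )
        elif local == "EllipsoidGate":
            dims, mean, cov, d2 = [], [], [], None
            for c in el:
                if not isinstance(c.tag, str):
                    continue
                if _local(c) == "dimension":
                    dims.append(_read_dimension(c))
                elif _local(c) == "mean":
                    mean = [float(_attr(v, "value")) for v in c
                            if isinstance(v.tag, str)]
                elif _local(c) == "covarianceMatrix":
                    cov = [
                        [float(_attr(v, "value")) for v in row if isinstance(v.tag, str)]
                        for row in c if isinstance(row.tag, str)
                    ]
                elif _local(c) == "distanceSquare":
                    d2 = float(_attr(c, "value"))
            strategy.add_gate(
                EllipsoidGate(
                    id=gid, parent_id=parent, dims=dims,
                    mean=np.asarray(mean), covariance=np.asarray(cov),
                    distance_square=d2,
                )
            )
        elif local == "BooleanGate":
            op_el = next(
                (c for c in el if isinstance(c.tag, str)
                 and _local(c) in ("and", "or", "not")), None,
            )
            if op_el is None:
                raise FormatError(f"BooleanGate {gid!r} lacks an and/or/not child")
            operands = [
                GateReference(
                    ref=_attr(r, "ref"),
                    complement=(_attr(r, "use-as-complement") == "true"),
                )
                for r in op_el if isinstance(r.tag, str)
            ]
            strategy.add_gate(
                BooleanGate(id=gid, parent_id=parent,
                            operator=_local(op_el).upper(), operands=operands)
            )
        else:
            raise UnsupportedFeatureError(f"unknown element {local!r} in Gating-ML")
    strategy.validate()
    return strategy


def strategies_equal(a: GatingStrategy, b: GatingStrategy, tol: float = 1e-12) -> bool:
    """Structural equality gate-by-gate, numeric values within ``tol``."""
    if set(a.gates) != set(b.gates) or set(a.transforms) != set(b.transforms) \
            or set(a.spectrum_matrices) != set(b.spectrum_matrices):
        return False
    for tid, ta in a.transforms.items():
        tb = b.transforms[tid]
        if ta.kind != tb.kind:
            return False
        if any(abs(getattr(ta, p) - getattr(tb, p)) > tol for p in "TMWA"):
            return False
    for mid, ma in a.spectrum_matrices.items():
        mb = b.spectrum_matrices[mid]
        if ma.detectors != mb.detectors or not np.allclose(ma.S, mb.S, atol=tol, rtol=0):
            return False
    for gid, ga in a.gates.items():
        gb = b.gates[gid]
        if type(ga) is not type(gb) or ga.parent_id != gb.parent_id:
            return False
        if isinstance(ga, BooleanGate):
            if ga.operator != gb.operator or ga.operands != gb.operands:
                return False
            continue
        if [
            (d.channel_name, d.transform_ref, d.compensation_ref) for d in ga.dims
        ] != [(d.channel_name, d.transform_ref, d.compensation_ref) for d in gb.dims]:
            return False
        if isinstance(ga, RectangleGate):
            for da, db in zip(ga.dims, gb.dims):
                for pa, pb in ((da.min, db.min), (da.max, db.max)):
                    if math.isinf(pa) != math.isinf(pb):
                        return False
                    if math.isfinite(pa) and abs(pa - pb) > tol:
                        return False
        elif isinstance(ga, PolygonGate):
            if not np.allclose(ga.vertices, gb.vertices, atol=tol, rtol=0):
                return False
        elif isinstance(ga, EllipsoidGate):
            if not (
                np.allclose(ga.mean, gb.mean, atol=tol, rtol=0)
                and np.allclose(ga.covariance, gb.covariance, atol=tol, rtol=0)
                and abs(ga.distance_square - gb.distance_square) <= tol
            ):
                return False
    return True
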