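"""Gate geometry, hierarchy semantics, and Gating-ML round-trips."""

import math

import numpy as np
import pytest

from cytostd.compensation import SpilloverMatrix
from cytostd.errors import (
    ChannelError,
    GateReferenceError,
    UnsupportedFeatureError,
    ValidationError,
)
from cytostd.fcs import make_dataset
from cytostd.gating import (
    BooleanGate,
    Dimension,
    EllipsoidGate,
    GateReference,
    GatingStrategy,
    PolygonGate,
    RectangleGate,
    _EvalContext,
    _own_membership,
    evaluate_all,
    evaluate_gate,
    points_in_polygon,
    read_gatingml,
    strategies_equal,
    write_gatingml,
)
from cytostd.transforms import Transform, apply_transform


def crossing_number_oracle(px, py, vertices):
    """Independent point-in-polygon classifier (PNPOLY formulation)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i - 1) % n]
        if (y1 > py) != (y2 > py) and px < (x2 - x1) * (py - y1) / (y2 - y1) + x1:
            inside = not inside
    return inside


def unit_square_strategy():
    s = GatingStrategy()
    s.add_gate(
        RectangleGate(
            id="sq",
            dims=[Dimension("X", min=0.0, max=1.0), Dimension("Y", min=0.0, max=1.0)],
        )
    )
    return s


class TestGeometry:
    def test_rectangle_min_inclusive_max_exclusive(self, small_dataset):
        got = evaluate_gate(unit_square_strategy(), "sq", small_dataset)
        # events: (0.5,0.5) in, (2,2) out, (0,0) in (min edge), (1,1) out (max edge)
        np.testing.assert_array_equal(got, [True, False, True, False])

    def test_polygon_against_crossing_number_oracle(self, rng):
        """50 random simple-ish polygons x 1000 points, zero disagreements."""
        for _ in range(50):
            n_vert = int(rng.integers(3, 13))
            # star-shaped construction: random radii at sorted angles
            ang = np.sort(rng.uniform(0, 2 * math.pi, size=n_vert))
            rad = rng.uniform(0.3, 1.5, size=n_vert)
            verts = list(zip(rad * np.cos(ang), rad * np.sin(ang)))
            px = rng.uniform(-2, 2, size=1000)
            py = rng.uniform(-2, 2, size=1000)
            got = points_in_polygon(px, py, verts)
            want = [crossing_number_oracle(x, y, verts) for x, y in zip(px, py)]
            np.testing.assert_array_equal(got, want)

    def test_self_intersecting_polygon_even_odd(self):
        # bow-tie: the crossing point region keeps even-odd semantics
        verts = [(0, 0), (2, 2), (2, 0), (0, 2)]
        assert points_in_polygon(
            np.array([0.5]), np.array([1.0]), verts
        )[0]  # left lobe
        assert not points_in_polygon(np.array([1.0]), np.array([1.75]), verts)[0]

    def test_polygon_boundary_inclusive(self):
        verts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        on = points_in_polygon(np.array([0.0, 1.0, 0.5]), np.array([0.5, 0.5, 1.0]), verts)
        assert on.all()

    def test_zero_area_polygon_rejected(self):
        with pytest.raises(ValidationError, match="zero area"):
            PolygonGate(
                id="bad", dims=[Dimension("X"), Dimension("Y")],
                vertices=[(0, 0), (1, 1), (2, 2)],
            )

    def test_ellipsoid_boundary_inclusive(self):
        s = GatingStrategy()
        s.add_gate(
            EllipsoidGate(
                id="e", dims=[Dimension("X"), Dimension("Y")],
                mean=np.zeros(2), covariance=np.eye(2), distance_square=1.0,
            )
        )
        ds = make_dataset(np.array([[1.0, 0.0], [1.01, 0.0]]), ["X", "Y"])
        np.testing.assert_array_equal(evaluate_gate(s, "e", ds), [True, False])


class TestHierarchyAndBoolean:
    def _two_blob_ds(self, rng, n=500):
        events = rng.uniform(-2, 2, size=(n, 2))
        return make_dataset(events, ["X", "Y"])

    def test_child_clipped_to_parent(self, rng):
        """A child whose region contains the parent's cannot exceed it."""
        s = GatingStrategy()
        s.add_gate(RectangleGate(id="p", dims=[Dimension("X", min=0.0, max=1.0)]))
        s.add_gate(
            RectangleGate(id="c", parent_id="p",
                          dims=[Dimension("X", min=-10.0, max=10.0)])
        )
        ds = self._two_blob_ds(rng)
        _, stats = evaluate_all(s, ds)
        assert stats["c"]["count"] == stats["p"]["count"]
        assert stats["c"]["pct_of_parent"] == 100.0

    def test_not_gate_complements_total(self, rng):
        s = GatingStrategy()
        s.add_gate(RectangleGate(id="g", dims=[Dimension("X", min=0.0)]))
        s.add_gate(BooleanGate(id="ng", operator="NOT", operands=[GateReference("g")]))
        ds = self._two_blob_ds(rng)
        _, stats = evaluate_all(s, ds)
        assert stats["ng"]["count"] == ds.n_events - stats["g"]["count"]

    def test_de_morgan_on_random_gates(self, rng):
        for _ in range(20):
            lo_a, lo_b = rng.uniform(-1, 0, size=2)
            hi_a, hi_b = rng.uniform(0, 1, size=2)
            s = GatingStrategy()
            s.add_gate(RectangleGate(id="A", dims=[Dimension("X", min=lo_a, max=hi_a)]))
            s.add_gate(RectangleGate(id="B", dims=[Dimension("Y", min=lo_b, max=hi_b)]))
            s.add_gate(BooleanGate(id="AandB", operator="AND",
                                   operands=[GateReference("A"), GateReference("B")]))
            s.add_gate(BooleanGate(id="notAandB", operator="NOT",
                                   operands=[GateReference("AandB")]))
            s.add_gate(
                BooleanGate(
                    id="notA_or_notB", operator="OR",
                    operands=[GateReference("A", complement=True),
                              GateReference("B", complement=True)],
                )
            )
            ds = self._two_blob_ds(rng, n=300)
            m, _ = evaluate_all(s, ds)
            np.testing.assert_array_equal(m["notAandB"], m["notA_or_notB"])

    def test_hierarchy_monotonic_on_random_strategies(self, rng):
        """Every gate's membership implies its parent's, elementwise."""
        ds = self._two_blob_ds(rng, n=400)
        for _ in range(10):
            s = GatingStrategy()
            ids = []
            for i in range(6):
                parent = None if not ids or rng.random() < 0.3 else str(rng.choice(ids))
                lo = float(rng.uniform(-1.5, 0.5))
                s.add_gate(
                    RectangleGate(
                        id=f"g{i}", parent_id=parent,
                        dims=[Dimension(str(rng.choice(["X", "Y"])), min=lo,
                                        max=lo + float(rng.uniform(0.2, 2.0)))],
                    )
                )
                ids.append(f"g{i}")
            m, _ = evaluate_all(s, ds)
            for gid in ids:
                pid = s.gates[gid].parent_id
                if pid is not None:
                    assert not np.any(m[gid] & ~m[pid])

    def test_declaration_order_irrelevant(self, rng):
        ds = self._two_blob_ds(rng, n=200)
        a = GatingStrategy()
        a.add_gate(RectangleGate(id="p", dims=[Dimension("X", min=0.0)]))
        a.add_gate(RectangleGate(id="c", parent_id="p", dims=[Dimension("Y", min=0.0)]))
        b = GatingStrategy()
        b.add_gate(RectangleGate(id="c", parent_id="p", dims=[Dimension("Y", min=0.0)]))
        b.add_gate(RectangleGate(id="p", dims=[Dimension("X", min=0.0)]))
        ma, _ = evaluate_all(a, ds)
        mb, _ = evaluate_all(b, ds)
        np.testing.assert_array_equal(ma["c"], mb["c"])

    def test_boolean_cycle_reports_path(self, rng):
        s = GatingStrategy()
        s.gates["a"] = BooleanGate(id="a", operator="NOT", operands=[GateReference("b")])
        s.gates["b"] = BooleanGate(id="b", operator="NOT", operands=[GateReference("a")])
        ds = self._two_blob_ds(rng, n=10)
        with pytest.raises(GateReferenceError, match="a -> b -> a"):
            evaluate_gate(s, "a", ds)

    def test_missing_channel_lists_available(self, small_dataset):
        s = GatingStrategy()
        s.add_gate(RectangleGate(id="g", dims=[Dimension("NOPE", min=0.0)]))
        with pytest.raises(ChannelError, match="X, Y"):
            evaluate_gate(s, "g", small_dataset)


class TestTransformedGates:
    def test_rectangle_data_vs_display_space_agree(self, rng):
        """Inverse-transformed bounds in data space == display-space test."""
        t = Transform(id="lg", kind="logicle", T=262144, W=0.5, M=4.5, A=0)
        s = GatingStrategy()
        s.add_transform(t)
        s.add_gate(
            RectangleGate(
                id="r",
                dims=[Dimension("X", transform_ref="lg", min=0.3, max=0.8)],
            )
        )
        x = rng.lognormal(6, 2, size=2000)
        ds = make_dataset(x[:, None], ["X"])
        data_space = evaluate_gate(s, "r", ds)
        ctx = _EvalContext(s, ds)
        display_space = _own_membership(s.gates["r"], ctx, rectangle_space="display")
        np.testing.assert_array_equal(data_space, display_space)

    def test_gate_with_explicit_spectrum_matrix(self):
        """Dimension-level compensation is applied before the geometry."""
        sp = SpilloverMatrix(["FL1", "FL2"], np.array([[1, 0.2], [0.0, 1]]))
        s = GatingStrategy()
        s.add_spectrum_matrix("cm", sp)
        s.add_gate(
            RectangleGate(
                id="g",
                dims=[Dimension("FL2", compensation_ref="cm", min=50.0, max=150.0)],
            )
        )
        true = np.array([[100.0, 100.0], [100.0, 300.0]])
        observed = np.array([[100.0, 120.0], [100.0, 320.0]])  # FL2 += 0.2*FL1
        ds = make_dataset(observed, ["FL1", "FL2"])
        np.testing.assert_array_equal(evaluate_gate(s, "g", ds), [True, False])
        assert (true[:, 1] >= 50).all()  # oracle: gate on the true signal


class TestXml:
    def test_single_rectangle_roundtrip(self):
        s = GatingStrategy()
        s.add_gate(
            RectangleGate(
                id="scatter",
                dims=[Dimension("FSC-A", min=1e4, max=2e5), Dimension("SSC-A", min=5e3)],
            )
        )
        assert strategies_equal(s, read_gatingml(write_gatingml(s)))

    def test_full_strategy_roundtrip(self):
        """6 gates over 3 levels + 2 transforms + 1 spectrum matrix."""
        t1 = Transform(id="lg", kind="logicle", T=262144, W=0.5, M=4.5, A=0)
        t2 = Transform(id="as", kind="fasinh", T=1000, M=4, A=1)
        s = GatingStrategy()
        s.add_transform(t1).add_transform(t2)
        s.add_spectrum_matrix(
            "cm", SpilloverMatrix(["FL1", "FL2"], np.array([[1, 0.1], [0.05, 1]]))
        )
        s.add_gate(RectangleGate(id="live", dims=[Dimension("FSC-A", min=1e4)]))
        s.add_gate(
            PolygonGate(
                id="lymph", parent_id="live",
                dims=[Dimension("FL1", transform_ref="lg", compensation_ref="cm"),
                      Dimension("FL2", transform_ref="as", compensation_ref="cm")],
                vertices=[(0.1, 0.1), (0.9, 0.15), (0.5, 0.8)],
            )
        )
        s.add_gate(
            EllipsoidGate(
                id="blast", parent_id="lymph",
                dims=[Dimension("FL1", transform_ref="lg")],
                mean=np.array([0.5]), covariance=np.array([[0.01]]),
                distance_square=2.0,
            )
        )
        s.add_gate(RectangleGate(id="other", parent_id="live",
                                 dims=[Dimension("SSC-A", max=1e3)]))
        s.add_gate(BooleanGate(id="notlive", operator="NOT",
                               operands=[GateReference("live")]))
        s.add_gate(
            BooleanGate(
                id="either", operator="OR",
                operands=[GateReference("lymph"),
                          GateReference("other", complement=True)],
            )
        )
        xml = write_gatingml(s)
        assert strategies_equal(s, read_gatingml(xml))

    def test_unknown_element_named_in_error(self):
        xml = (
            '<g:Gating-ML xmlns:g="http://www.isac-net.org/std/Gating-ML/v2.0/gating">'
            '<g:QuadrantGate g:id="q"/></g:Gating-ML>'
        )
        with pytest.raises(UnsupportedFeatureError, match="QuadrantGate"):
            read_gatingml(xml)

    def test_dangling_parent_listed(self):
        xml = (
            '<g:Gating-ML xmlns:g="http://www.isac-net.org/std/Gating-ML/v2.0/gating" '
            'xmlns:d="http://www.isac-net.org/std/Gating-ML/v2.0/datatypes">'
            '<g:RectangleGate g:id="a" g:parent_id="ghost">'
            '<g:dimension g:min="0"><d:fcs-dimension d:name="X"/></g:dimension>'
            "</g:RectangleGate></g:Gating-ML>"
        )
        with pytest.raises(GateReferenceError, match="ghost"):
            read_gatingml(xml)

    def test_v15_namespace_accepted(self):
        xml = (
            '<g:Gating-ML xmlns:g="http://www.isac-net.org/std/Gating-ML/v1.5/gating" '
            'xmlns:d="http://www.isac-net.org/std/Gating-ML/v2.0/datatypes">'
            '<g:RectangleGate g:id="a">'
            '<g:dimension g:min="0" g:max="10"><d:fcs-dimension d:name="X"/></g:dimension>'
            "</g:RectangleGate></g:Gating-ML>"
        )
        s = read_gatingml(xml)
        assert "a" in s.gates

    def test_foreign_namespace_rejected(self):
        with pytest.raises(Exception, match="namespace"):
            read_gatingml('<Gating-ML xmlns="http://example.org/x"/>')
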