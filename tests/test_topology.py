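"""Knot identification: KMT, closures, Alexander invariants, writhe, cores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helknot.topology import (
    INVARIANT_TABLE,
    alexander_invariants,
    classify_knot,
    classify_knot_stochastic,
    close_chain,
    kmt_simplify,
    locate_knot_core,
    writhe,
    analyze_chain,
    chirality_sign,
    TopologyError,
)
from helknot.knot_factory import generate_knot, torus_knot_coords


def torus_curve(p, q, n=200, radius=2.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius + np.cos(p * t)
    return np.column_stack([r * np.cos(q * t), r * np.sin(q * t),
                            np.sin(p * t)])


class TestKMT:
    def test_planar_convex_polygon_reduces_to_triangle(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        poly = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        red = kmt_simplify(poly, closed=True)
        assert len(red) == 3

    def test_idempotent(self):
        c = torus_curve(3, 2)
        once = kmt_simplify(c, True)
        twice = kmt_simplify(once, True)
        assert np.array_equal(once, twice)

    def test_preserves_classification(self):
        c = torus_curve(3, 2)
        red = kmt_simplify(c, True)
        assert len(red) < len(c)
        assert classify_knot(red, closed=True) == "3_1"


class TestAlexander:
    # expected pairs computed from published Alexander polynomials,
    # denominator-cleared and evaluated at t = -1, -2 (torus knots via
    # Delta_{T(p,q)} = (t^{pq}-1)(t-1)/((t^p-1)(t^q-1)))
    @pytest.mark.parametrize("p,q,expected", [
        (1, 1, (1, 1)),
        (3, 2, (3, 7)),
        (5, 2, (5, 31)),
        (7, 2, (7, 127)),
        (3, 4, (3, 91)),
        (3, 5, (1, 331)),
    ])
    def test_torus_knot_invariants(self, p, q, expected):
        assert alexander_invariants(torus_curve(p, q)) == expected

    def test_determinant_alone_cannot_separate_10_124_from_unknot(self):
        d1, d2 = alexander_invariants(torus_curve(3, 5))
        assert d1 == 1 and d2 == 331

    def test_invariance_under_rotation_and_scaling(self):
        rng = np.random.default_rng(0)
        c = torus_curve(3, 2)
        ref = alexander_invariants(c)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert alexander_invariants(3.7 * c @ q.T) == ref

    def test_mirror_blindness(self):
        c = torus_curve(3, 2)
        m = c.copy()
        m[:, 2] *= -1
        assert alexander_invariants(m) == alexander_invariants(c)

    def test_sympy_oracle_cross_check(self):
        """Independent symbolic evaluation of the bundled invariant table."""
        import sympy as sp

        t = sp.symbols("t")
        polys = {
            "3_1": t - 1 + 1 / t,
            "4_1": -t + 3 - 1 / t,
            "5_1": t**2 - t + 1 - 1 / t + 1 / t**2,
            "5_2": 2 * t - 3 + 2 / t,
            "6_1": 2 * t - 5 + 2 / t,
            "6_3": t**2 - 3 * t + 5 - 3 / t + 1 / t**2,
            "7_1": t**3 - t**2 + t - 1 + 1 / t - 1 / t**2 + 1 / t**3,
            "7_4": 4 * t - 7 + 4 / t,
            "8_18": -t**3 + 5 * t**2 - 10 * t + 13 - 10 / t + 5 / t**2
                    - 1 / t**3,
        }
        table_by_label = {v: k for k, v in INVARIANT_TABLE.items()}
        for label, poly in polys.items():
            cleared = sp.Poly(sp.expand(poly * t**3), t)
            coeffs = [int(c) for c in cleared.all_coeffs()]
            while coeffs and coeffs[-1] == 0:
                coeffs.pop()
            d1 = abs(int(np.polyval(coeffs, -1)))
            d2 = abs(int(np.polyval(coeffs, -2)))
            assert table_by_label[label] == (d1, d2), label


class TestClosure:
    def test_straight_segment_closes_to_unknot(self):
        seg = np.column_stack([np.zeros(20), np.zeros(20),
                               np.arange(20.0)])
        for method in ("direct", "out_and_around"):
            assert classify_knot(seg, closed=False, closure=method) == "unknot"

    def test_nearly_closed_ring_same_label_both_methods(self):
        c = torus_curve(3, 2, n=150)[:-1]      # ends ~one bond apart
        for method in ("direct", "out_and_around"):
            assert classify_knot(c, closed=False, closure=method) == "3_1"

    def test_stretched_knotoid_out_and_around(self, trefoil_knotoid):
        assert classify_knot(trefoil_knotoid.positions, closed=False) == "3_1"

    def test_stochastic_closure_majority(self, trefoil_knotoid):
        lbl = classify_knot_stochastic(trefoil_knotoid.positions,
                                       m_closures=40)
        assert lbl == "3_1"


class TestWrithe:
    def test_planar_closed_polygon_zero(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        poly = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        assert writhe(poly, closed=True) == pytest.approx(0.0, abs=1e-10)

    def test_mirror_negation_exact(self):
        c = torus_curve(3, 2)
        m = c.copy()
        m[:, 2] *= -1
        assert writhe(m, True) == pytest.approx(-writhe(c, True), rel=1e-12)

    def test_quadrature_oracle(self):
        """Segment-pair solid-angle sum matches a dense numerical Gauss
        double integral on a smooth curve."""
        n = 80
        c = torus_curve(3, 2, n=n)
        wr_poly = writhe(c, True)
        # brute-force midpoint quadrature of the Gauss linking integral
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = c
        tang = np.roll(pts, -1, axis=0) - pts
        mids = pts + 0.5 * tang
        total = 0.0
        for i in range(n):
            d = mids[i] - mids
            r3 = np.linalg.norm(d, axis=1) ** 3
            cr = np.cross(tang[i], tang)
            contrib = (cr * d).sum(axis=1)
            mask = np.ones(n, bool)
            mask[[i, (i - 1) % n, (i + 1) % n]] = False
            total += (contrib[mask] / r3[mask]).sum()
        wr_quad = total / (4 * np.pi)
        assert wr_poly == pytest.approx(wr_quad, abs=0.15)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(TopologyError):
            writhe(np.zeros((3, 3)), closed=False)


class TestClassify:
    def test_generated_torus_knot(self):
        st_ = torus_knot_coords(3, 2, 100)
        assert classify_knot(st_.positions, closed=True) == "3_1"

    def test_chirality_from_writhe_only(self):
        pos = generate_knot("3_1", 100, chirality=+1).positions
        neg = generate_knot("3_1", 100, chirality=-1).positions
        assert classify_knot(pos, True) == classify_knot(neg, True) == "3_1"
        assert chirality_sign("3_1", writhe(pos, True)) == 1
        assert chirality_sign("3_1", writhe(neg, True)) == -1
        assert chirality_sign("4_1", 0.3) == 0    # amphichiral: no prefix

    def test_straight_chain_unknot(self):
        seg = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        assert classify_knot(seg, closed=False) == "unknot"


class TestLocateCore:
    def test_unknotted_chain_rejected(self):
        seg = np.column_stack([np.zeros(20), np.zeros(20), np.arange(20.0)])
        with pytest.raises(TopologyError):
            locate_knot_core(seg)

    def test_localized_trefoil_core(self, trefoil_knotoid):
        i0, i1 = locate_knot_core(trefoil_knotoid.positions)
        n = trefoil_knotoid.n_beads
        assert 1 <= i0 < i1 <= n
        assert 10 <= i1 - i0 + 1 <= 60        # localized, not the whole chain
        core = trefoil_knotoid.positions[i0 - 1:i1]
        assert classify_knot(core, closed=False) == "3_1"

    def test_mirror_symmetry_of_core(self, trefoil_knotoid):
        pts = trefoil_knotoid.positions
        mirrored = pts.copy()
        mirrored[:, 1] *= -1
        assert locate_knot_core(pts) == locate_knot_core(mirrored)

    def test_record_fields_consistent(self, trefoil_knotoid):
        rec = analyze_chain(trefoil_knotoid.positions, circular=False)
        assert rec.label == "3_1"
        assert rec.chirality_sign == int(np.sign(rec.writhe))
        assert rec.prefixed_label in ("<+>3_1", "<->3_1")
        assert rec.i_middle == int(round((rec.i_start + rec.i_end) / 2))
        assert rec.alexander_pair == (3, 7)


class TestRigidMotionProperty:
    @settings(max_examples=8, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariants_stable_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        c = torus_curve(3, 2, n=120)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:       # keep it a proper rotation
            q[:, 0] *= -1
        moved = c @ q.T + rng.normal(scale=5.0, size=3)
        assert alexander_invariants(moved) == (3, 7)
        assert writhe(moved, True) == pytest.approx(writhe(c, True), rel=1e-6)
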