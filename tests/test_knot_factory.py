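"""Knot generation, fixtures, resampling, knotoid prep, channel insertion."""

import numpy as np
import pytest

from helknot.knot_factory import (
    KNOT_CATALOG,
    ChainState,
    KnotGenerationError,
    braid_closure_coords,
    generate_knot,
    load_knot_fixture,
    pretzel_coords,
    resample_equal_arclength,
    torus_knot_coords,
)
from helknot.topology import classify_knot, writhe, alexander_invariants


class TestTorusKnots:
    def test_unknot_from_1_1(self):
        st = torus_knot_coords(1, 1, 60)
        assert alexander_invariants(st.positions) == (1, 1)

    def test_trefoil_classifies(self):
        st = torus_knot_coords(3, 2, 100)
        assert classify_knot(st.positions, closed=True) == "3_1"

    def test_link_rejected(self):
        with pytest.raises(KnotGenerationError, match="link"):
            torus_knot_coords(4, 2, 100)

    def test_mirror_flips_writhe_sign_only(self):
        st = torus_knot_coords(3, 2, 100)
        mirrored = st.positions.copy()
        mirrored[:, 2] *= -1
        w0 = writhe(st.positions, True)
        w1 = writhe(mirrored, True)
        assert w1 == pytest.approx(-w0)
        assert abs(w1) == pytest.approx(abs(w0))


class TestResampling:
    @pytest.mark.parametrize("closed", [True, False])
    def test_contour_length_exact(self, closed):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(57, 3)), axis=0)
        if closed:
            t = np.linspace(0, 2 * np.pi, 57, endpoint=False)
            pts = np.column_stack([5 * np.cos(t), 5 * np.sin(t), np.sin(3 * t)])
        out = resample_equal_arclength(pts, 80, closed=closed)
        if closed:
            chords = np.linalg.norm(np.roll(out, -1, axis=0) - out, axis=1)
            assert chords.sum() == pytest.approx(80.0, abs=1e-6)
        else:
            chords = np.linalg.norm(np.diff(out, axis=0), axis=1)
            assert chords.sum() == pytest.approx(79.0, abs=1e-6)
        assert chords.min() > 0.5 and chords.max() < 1.5


class TestCatalog:
    @pytest.mark.parametrize("label", sorted(KNOT_CATALOG))
    def test_every_entry_generates_and_classifies(self, label):
        st = generate_knot(label, 100)
        assert classify_knot(st.positions, closed=True) == label
        st.validate()

    def test_requested_chirality_by_writhe(self):
        for label in ("3_1", "5_1"):
            pos = generate_knot(label, 100, chirality=+1)
            neg = generate_knot(label, 100, chirality=-1)
            assert writhe(pos.positions, True) > 0
            assert writhe(neg.positions, True) < 0

    def test_amphichiral_mean_writhe_near_zero(self):
        # 4_1, 6_3, 8_18 embeddings carry no systematic writhe
        for label in ("4_1", "6_3", "8_18"):
            w = writhe(generate_knot(label, 140).positions, True)
            assert abs(w) < 0.5

    def test_unknown_label_rejected(self):
        with pytest.raises(KnotGenerationError, match="available"):
            generate_knot("9_99")


class TestBuilders:
    def test_braid_closure_multi_component_rejected(self):
        # sigma_1^2 on 3 strands closes to a knot + a split circle
        with pytest.raises(KnotGenerationError, match="components"):
            braid_closure_coords([1, 1], 3, 100)

    def test_pretzel_even_twists_rejected(self):
        with pytest.raises(KnotGenerationError, match="odd"):
            pretzel_coords(2, 3, 1)

    def test_pretzel_trefoil(self):
        st = pretzel_coords(1, 1, 1, n_beads=100)
        assert classify_knot(st.positions, closed=True) == "3_1"


class TestFixtures:
    @pytest.mark.parametrize("name", ["4_1", "5_2", "6_1", "6_3", "7_4",
                                      "8_18", "10_124"])
    def test_fixture_loads_and_classifies(self, name):
        st = load_knot_fixture(name, n_beads=100)
        assert classify_knot(st.positions, closed=True) == name
        chords = st.bond_lengths()
        assert chords.sum() == pytest.approx(100.0, abs=1e-6)

    def test_missing_fixture(self):
        with pytest.raises(KnotGenerationError, match="no bundled"):
            load_knot_fixture("3_1")      # torus knots are generated, not bundled


class TestKnotoid:
    def test_knotoid_keeps_knot_type_and_orientation(self, trefoil_knotoid):
        st = trefoil_knotoid
        assert not st.circular
        assert st.tether_index == 0
        assert st.positions[0, 2] < st.positions[-1, 2]
        assert classify_knot(st.positions, closed=False, closure="axis") \
            == "3_1"

    def test_unknotted_ring_yields_no_core(self):
        from helknot.knot_factory import make_knotoid
        from helknot.topology import locate_knot_core, TopologyError

        ring = generate_knot("unknot", 60)
        st = make_knotoid(ring, seed=4, max_stretch_steps=60_000)
        assert not st.circular
        assert classify_knot(st.positions, closed=False) == "unknot"
        with pytest.raises(TopologyError, match="no core"):
            locate_knot_core(st.positions)

    def test_circular_input_required(self, trefoil_knotoid):
        from helknot.knot_factory import make_knotoid

        with pytest.raises(KnotGenerationError, match="circular"):
            make_knotoid(trefoil_knotoid)


class TestChainState:
    def test_strict_bond_bounds(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5),
                               np.array([0.0, 1.0, 2.0, 3.0, 4.7])])
        st = ChainState(pts, np.zeros_like(pts), circular=False)
        with pytest.raises(KnotGenerationError, match="bond lengths"):
            st.validate()
        st.positions[-1, 2] = 4.0
        st.validate()

    def test_circular_tether_forbidden(self):
        st = generate_knot("3_1", 100)
        st.tether_index = 3
        with pytest.raises(KnotGenerationError, match="tether"):
            st.validate()


class TestInsertion:
    def test_trefoil_into_default_helix(self, confined_antichiral):
        """End-to-end check through the session fixture: the confined run
        starts from an inserted state that stayed 3_1."""
        labels = {r.label for r in confined_antichiral.knot_records
                  if r is not None}
        assert labels == {"3_1"}

    def test_all_beads_inside_tube(self, trefoil_knotoid):
        from helknot.knot_factory import insert_chain_into_channel
        from helknot.channel import HelicalChannelSpec, wall_distance

        spec = HelicalChannelSpec(r_ch=3.0, r_h=1.5, pitch_k=1.5,
                                  handedness=-1, n_turns=12)
        st, geom = insert_chain_into_channel(trefoil_knotoid, spec,
                                             rng_seed=31)
        assert classify_knot(st.positions, closed=False, closure="axis") \
            == "3_1"
        d = max(wall_distance(p, spec) for p in st.positions)
        assert d < 0.0
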