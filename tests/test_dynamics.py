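"""Langevin integrator oracles, protocols, and symmetry properties."""

import numpy as np
import pytest

from helknot import _kernels
from helknot import dynamics as dyn
from helknot.dynamics import (
    LangevinParams,
    ProtocolConfig,
    flip_rule,
    run_protocol,
)
from helknot.forcefield import ForceFieldParams, total_energy
from helknot.knot_factory import ChainState
from helknot.topology import KnotRecord

NO_WALL = _kernels.build_wall_cells(np.zeros((0, 3)), False, 0.0)


def _single_bead_run(n_blocks, block, fext, kT, seed):
    wall, cs, cc, ci, go, gn, gs = NO_WALL
    pos = np.zeros((1, 3))
    vel = np.zeros((1, 3))
    _kernels.seed_rng(seed)
    samples = []
    for _ in range(n_blocks):
        _kernels.run_baoab(pos, vel, block, 0.01, 1.0, kT, 1.0, -1, False,
                           90.0, 1.0, 15.0, 1.0, 1.0, fext, 1.0, 0.0,
                           wall, cs, cc, ci, go, gn, gs, False, 0.0, 0.0,
                           0.0, np.zeros(3), np.zeros(3), np.ones(3))
        samples.append(pos[0].copy())
    return np.array(samples)


class TestIntegratorOracles:
    def test_einstein_relation_single_bead(self):
        """Free-bead diffusivity D = kT/(m gamma) = 1 sigma^2/tau to 5%."""
        traj = _single_bead_run(250, 5000, 0.0, 1.0, 42)
        disp = np.diff(traj, axis=0)
        d_est = (disp ** 2).sum(axis=1).mean() / (6 * 50.0)
        assert d_est == pytest.approx(1.0, rel=0.05)

    def test_mobility_single_bead(self):
        """Deterministic terminal drift v = F/(m gamma) at kT = 0."""
        wall, cs, cc, ci, go, gn, gs = NO_WALL
        pos = np.zeros((1, 3))
        vel = np.zeros((1, 3))
        _kernels.seed_rng(1)
        _kernels.run_baoab(pos, vel, 100_000, 0.01, 1.0, 0.0, 1.0, -1, False,
                           90.0, 1.0, 15.0, 1.0, 1.0, 0.1, 1.0, 0.0,
                           wall, cs, cc, ci, go, gn, gs, False, 0.0, 0.0,
                           0.0, np.zeros(3), np.zeros(3), np.ones(3))
        assert pos[0, 2] / 1000.0 == pytest.approx(0.1, rel=0.005)

    def test_gamma_zero_no_noise_is_velocity_verlet(self):
        """At gamma = 0 the scheme reduces to velocity Verlet: over 1e4
        steps the total energy shows no secular drift (< 1e-4 relative
        between window means; the symplectic oscillation itself is
        O((dt*omega)^2))."""
        rng = np.random.default_rng(4)
        n = 20
        pos = np.column_stack([np.zeros(n), np.zeros(n),
                               np.arange(n, dtype=float)])
        pos += rng.normal(scale=0.02, size=(n, 3))
        vel = rng.normal(scale=0.3, size=(n, 3))
        params = ForceFieldParams(f_ext=0.0, k_s=10.0)
        state = ChainState(pos.copy(), vel.copy(), circular=False)
        lp = LangevinParams(gamma=1e-12, kT=0.0, seed=0)
        dyn.seed(0)
        energies = []
        for _ in range(40):
            e_pot = total_energy(state.positions, False, params)
            e_kin = 0.5 * (state.velocities ** 2).sum()
            energies.append(e_pot + e_kin)
            dyn.langevin_step(state, lp, params, None, n_steps=250)
        energies = np.array(energies)
        # secular drift = regression slope x run length (the bounded
        # symplectic oscillation, std ~2e-4, averages out of the fit)
        k = np.arange(len(energies))
        slope = np.polyfit(k, energies, 1)[0]
        drift = abs(slope * len(energies)) / energies.mean()
        assert drift < 1e-4

    def test_tethered_bead_frozen(self):
        pos = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        state = ChainState(pos.copy(), np.zeros((10, 3)), circular=False,
                           tether_index=0)
        dyn.seed(3)
        dyn.langevin_step(state, LangevinParams(seed=3), ForceFieldParams(),
                          None, n_steps=5000)
        assert np.array_equal(state.positions[0], pos[0])
        assert not np.allclose(state.positions[1:], pos[1:])


class TestPersistenceLength:
    def test_bond_correlation_decay_gives_45_nm(self):
        """k_theta = 15 eps0/rad^2 with 3 nm beads -> P_l = 45 nm within 10%
        from the initial decay of tangent correlations (excluded volume
        inflates the long-range tail, so the first-neighbour decay is the
        clean estimator)."""
        n = 100
        pts = np.column_stack([np.zeros(n), np.zeros(n),
                               np.arange(n, dtype=float)])
        state = ChainState(pts, np.zeros_like(pts), circular=False)
        ff = ForceFieldParams(f_ext=0.0)
        lp = LangevinParams(seed=9)
        dyn.seed(9)
        dyn.langevin_step(state, lp, ff, None, n_steps=40_000)
        acc = 0.0
        cnt = 0
        for _ in range(40):
            dyn.langevin_step(state, lp, ff, None, n_steps=2000)
            b = np.diff(state.positions, axis=0)
            b /= np.linalg.norm(b, axis=1)[:, None]
            acc += (b[:-1] * b[1:]).sum(axis=1).mean()
            cnt += 1
        p_beads = -1.0 / np.log(acc / cnt)
        assert p_beads * 3.0 == pytest.approx(45.0, rel=0.10)


class TestFlipRule:
    def _rec(self, i0, i1):
        return KnotRecord("3_1", 1, i0, i1, 3.3, (3, 7))

    def _state(self, tether):
        pos = np.column_stack([np.zeros(100), np.zeros(100),
                               np.arange(100.0)])
        return ChainState(pos, np.zeros_like(pos), circular=False,
                          tether_index=tether, force_sign=1)

    def test_centered_knot_unchanged(self):
        st = self._state(0)
        assert not flip_rule(self._rec(40, 60), st, ProtocolConfig())
        assert st.tether_index == 0 and st.force_sign == 1

    def test_knot_at_free_end_triggers_flip(self):
        st = self._state(0)
        assert flip_rule(self._rec(70, 98), st, ProtocolConfig())
        assert st.tether_index == 99
        assert st.force_sign == -1

    def test_double_flip_restores_sign(self):
        st = self._state(0)
        flip_rule(self._rec(70, 98), st, ProtocolConfig())
        flip_rule(self._rec(2, 30), st, ProtocolConfig())
        assert st.tether_index == 0
        assert st.force_sign == 1

    def test_knot_at_tethered_end_does_not_refire(self):
        st = self._state(99)
        st.force_sign = -1
        assert not flip_rule(self._rec(70, 98), st, ProtocolConfig())


class TestMirrorEquivariance:
    def test_deterministic_mirror_trajectories(self):
        """Reflected initial state + reflected noise stream gives the
        bead-for-bead mirrored trajectory."""
        rng = np.random.default_rng(12)
        pos = np.cumsum(rng.normal(scale=0.5, size=(30, 3)), axis=0)
        a = ChainState(pos.copy(), np.zeros_like(pos), circular=False,
                       tether_index=0)
        b = ChainState(pos.copy() * [1, -1, 1], np.zeros_like(pos),
                       circular=False, tether_index=0)
        ff = ForceFieldParams()
        lp = LangevinParams(seed=5)
        dyn.seed(5)
        dyn.langevin_step(a, lp, ff, None, n_steps=2000)
        dyn.seed(5)
        dyn.langevin_step(b, lp, ff, None, n_steps=2000,
                          noise_reflect=(1.0, -1.0, 1.0))
        assert np.allclose(b.positions, a.positions * [1, -1, 1],
                           atol=1e-10)


class TestRunProtocol:
    def test_deterministic_given_seed(self, trefoil_knotoid):
        proto = ProtocolConfig(total_steps=20_000, sample_every=1000,
                               n_replicas=1)
        t1 = run_protocol(trefoil_knotoid, None, proto,
                          LangevinParams(seed=77))
        t2 = run_protocol(trefoil_knotoid, None, proto,
                          LangevinParams(seed=77))
        assert np.array_equal(t1.positions, t2.positions)
        assert t1.metadata["flips"] == t2.metadata["flips"]

    def test_frame_count_and_monotone_times(self, free_space_run):
        proto = free_space_run.metadata["protocol"]
        expected = proto["total_steps"] // proto["sample_every"] + 1
        assert free_space_run.n_frames == expected
        assert np.all(np.diff(free_space_run.times) > 0)

    def test_topology_maintained_throughout(self, free_space_run):
        labels = {r.label for r in free_space_run.knot_records
                  if r is not None}
        assert labels == {"3_1"}

    def test_circular_chain_requires_periodic_channel(self, trefoil_knotoid):
        from helknot.channel import build_helical_tube, HelicalChannelSpec
        from helknot.knot_factory import generate_knot
        from helknot.dynamics import ProtocolError

        ring = generate_knot("3_1", 60)
        geom = build_helical_tube(HelicalChannelSpec(n_turns=2))
        proto = ProtocolConfig(total_steps=2000, sample_every=1000,
                               n_replicas=1)
        with pytest.raises(ProtocolError, match="periodic"):
            run_protocol(ring, geom, proto, LangevinParams(seed=1))
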