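"""Langevin integration and the knot-pulling experiment protocols.

The integrator is a BAOAB-class symplectic Langevin velocity-Verlet scheme
satisfying fluctuation-dissipation at each step (gamma = 0 and kT = 0
reduce it to plain velocity Verlet).  The tethered bead is frozen (an
infinite-mass limit).  Two protocols are supported:

* linear chains: one end tethered, constant force on every bead along the
  channel/stretch axis (z); when the knot core reaches a chain end, that
  end is tethered, the other released, and the force direction flipped
  (the sawtooth drift protocol);
* circular chains in a periodic channel: one-directional pull, no tether,
  no flipping.

Topology is re-checked at a fixed cadence; a failed check rewinds to the
last verified configuration and re-runs the block with fresh noise (strand
passages through transiently stretched bonds are discretisation artifacts,
so the sampled ensemble is conditioned on preserved topology), and the run
aborts only when reverts are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams
from .knot_factory import ChainState
from .channel import ChannelGeometry
from .topology import (
    KnotRecord,
    analyze_chain,
    classify_knot,
    TopologyError,
)


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters in reduced units.

    gamma is the damping rate in 1/tau (the bead Stokes time sets tau, so
    gamma = 1), kT the thermal energy in eps0.  Noise variance follows
    fluctuation-dissipation: 2 kT m gamma per unit time.
    """

    gamma: float = 1.0
    mass: float = 1.0
    kT: float = 1.0
    dt: float = 0.01
    seed: int = 2021

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.dt <= 0 or self.mass <= 0 or self.kT < 0:
            raise ValueError("invalid Langevin parameters")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ProtocolConfig:
    total_steps: int = 5_000_000
    sample_every: int = 1000
    topology_check_every: int = 1000   # ~1 us of physical time
    # beads from an end that triggers a flip; generous because core-boundary
    # estimates fluctuate by several beads and a knot hugging a chain end can
    # slide off between topology checks
    flip_margin: int = 8
    n_replicas: int = 5

    def __post_init__(self) -> None:
        if self.total_steps % self.sample_every:
            raise ValueError("sample_every must divide total_steps")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trajectory:
    """Sampled frames of one replica run."""

    times: np.ndarray                  # (F,) in tau, strictly increasing
    positions: np.ndarray              # (F, n, 3) in sigma
    force_signs: np.ndarray            # (F,)
    knot_records: list                 # KnotRecord or None per frame
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def knot_position_series(self):
        """(times, i_middle, force_sign) for frames with a located core."""
        ts, xs, ss = [], [], []
        for t, s, rec in zip(self.times, self.force_signs, self.knot_records):
            if rec is not None and rec.label not in ("unknot", "unresolved") \
                    and rec.i_start > 0:
                ts.append(t)
                xs.append(rec.i_middle)
                ss.append(s)
        return np.array(ts), np.array(xs, dtype=float), np.array(ss)


_NO_WALL = _kernels.build_wall_cells(np.zeros((0, 3)), False, 0.0)


def _wall_args(channel: ChannelGeometry | None):
    if channel is None:
        cells = _NO_WALL
        periodic = False
        period = 0.0
    else:
        periodic = channel.spec.periodic
        period = channel.spec.axial_length
        cells = _kernels.build_wall_cells(channel.wall, periodic, period)
    return cells, periodic, period


def langevin_step(state: ChainState, params: LangevinParams,
                  ff: ForceFieldParams = ForceFieldParams(),
                  channel: ChannelGeometry | None = None,
                  n_steps: int = 1,
                  f_end: float = 0.0,
                  cyl_radius: float = 0.0,
                  anchors: tuple | None = None,
                  noise_reflect=(1.0, 1.0, 1.0)) -> None:
    """Advance ``state`` in place by ``n_steps`` BAOAB steps.

    The caller is responsible for seeding (:func:`seed`) beforehand.
    """
    cells, periodic, period = _wall_args(channel)
    wall, cs, cc, ci, go, gn, gs = cells
    tether = -1 if state.tether_index is None else state.tether_index
    if anchors is None:
        k_anchor, a0, a1 = 0.0, np.zeros(3), np.zeros(3)
    else:
        k_anchor, a0, a1 = anchors
        a0 = np.asarray(a0, dtype=float)
        a1 = np.asarray(a1, dtype=float)
    status = _kernels.run_baoab(
        state.positions, state.velocities, n_steps, params.dt, params.gamma,
        params.kT, params.mass, tether, state.circular,
        ff.k_s, ff.r0, ff.k_theta, ff.wca_epsilon, ff.wca_sigma,
        ff.f_ext, float(state.force_sign), f_end,
        wall, cs, cc, ci, go, gn, gs, periodic, period, cyl_radius,
        float(k_anchor), a0, a1,
        np.asarray(noise_reflect, dtype=float))
    if status != 0:
        raise ProtocolError(f"integration failure (kernel status {status})")
    if not np.all(np.isfinite(state.positions)):
        raise ProtocolError("integration blow-up: non-finite coordinates")


def seed(value: int) -> None:
    """Seed the kernel RNG stream (once per trajectory)."""
    _kernels.seed_rng(int(value) % (2**31 - 1))


def flip_rule(knot: KnotRecord, state: ChainState,
              protocol: ProtocolConfig) -> bool:
    """Apply the tether/force flip when the knot core reaches a chain end.

    Returns True if a flip occurred.  The reached end becomes the tether,
    the other end is released, and the force sign is negated.  Applying the
    rule twice in a row restores the original sign (involution).
    """
    if state.circular or knot is None:
        return False
    n = state.n_beads
    near_start = knot.i_start - 1          # beads before the core
    near_end = n - knot.i_end              # beads after the core
    # the knot drifts away from the tether, so only the free end can be
    # "reached"; ignoring the tethered side keeps the rule from re-firing
    # every check while the knot still sits at the freshly tethered end
    if state.tether_index == 0:
        reached = near_end <= protocol.flip_margin
        new_tether = n - 1
    else:
        reached = near_start <= protocol.flip_margin
        new_tether = 0
    if not reached:
        return False
    state.tether_index = new_tether
    state.velocities[new_tether] = 0.0
    state.force_sign = -state.force_sign
    return True


def run_protocol(initial: ChainState,
                 channel: ChannelGeometry | None,
                 protocol: ProtocolConfig,
                 params: LangevinParams,
                 ff: ForceFieldParams = ForceFieldParams(),
                 locate_cores: bool = True,
                 max_reverts: int | None = None,
                 noise_reflect=(1.0, 1.0, 1.0)) -> Trajectory:
    """Run one replica of the pulling protocol and sample a trajectory.

    Topology is verified every ``topology_check_every`` steps.  The
    harmonic bonds of this discretisation allow rare thermal strand
    passages (instantaneous bond-length spikes of ~0.5 sigma open a
    low-barrier gap); a failed check therefore reverts the block to the
    last verified frame and re-runs it with fresh noise, so the sampled
    ensemble is the dynamics conditioned on preserved topology.  Every
    revert is logged in the trajectory metadata; the run aborts if reverts
    accumulate beyond ``max_reverts`` or one block fails repeatedly.
    For circular chains the channel must be periodic and no tether/flip
    logic is applied.
    """
    state = initial.copy()
    if state.circular:
        if channel is not None and not channel.spec.periodic:
            raise ProtocolError("circular chains need a periodic channel")
        state.tether_index = None
    else:
        if state.tether_index is None:
            raise ProtocolError("linear-chain protocol needs a tether")
    seed(params.seed)
    if max_reverts is None:
        max_reverts = protocol.total_steps // 5000 + 50
    ref_label = classify_knot(state.positions, closed=state.circular,
                              closure="direct" if state.circular else "axis")
    n_samples = protocol.total_steps // protocol.sample_every
    times = np.empty(n_samples + 1)
    frames = np.empty((n_samples + 1, state.n_beads, 3))
    signs = np.empty(n_samples + 1)
    records: list = [None] * (n_samples + 1)
    flips = []

    def _record(idx, step):
        times[idx] = step * params.dt
        frames[idx] = state.positions
        signs[idx] = state.force_sign

    def _analyze(step):
        # chains in this protocol are stretched along z (free space) or
        # confined in a z-axis channel: close along the axis so the closure
        # cannot thread back through the coiled chain
        try:
            if state.circular:
                return analyze_chain(state.positions, circular=True)
            if locate_cores:
                return analyze_chain(state.positions, circular=False,
                                     closure="axis")
            lbl = classify_knot(state.positions, closed=False,
                                closure="axis")
            return KnotRecord(lbl, 0, 1, state.n_beads, 0.0, (0, 0))
        except TopologyError as exc:
            raise ProtocolError(
                f"topology analysis failed at step {step}: {exc}") from exc

    _record(0, 0)
    records[0] = _analyze(0)
    check_every = max(1, protocol.topology_check_every // protocol.sample_every)
    reverts = []
    # ring buffer of verified checkpoints: repeated failures from the most
    # recent one (a passage-prone conformation) fall back further in time
    ckpts = [(0, state.positions.copy(), state.velocities.copy(),
              state.tether_index, state.force_sign)]
    s = 1
    block_fail = 0
    while s <= n_samples:
        langevin_step(state, params, ff, channel,
                      n_steps=protocol.sample_every,
                      noise_reflect=noise_reflect)
        step = s * protocol.sample_every
        if s % check_every == 0 or s == n_samples:
            rec = _analyze(step)
            if rec.label != ref_label:
                # rejected strand passage (or closure blip): revert
                block_fail += 1
                if len(reverts) >= max_reverts:
                    raise ProtocolError(
                        f"topology changed at step {step}: {ref_label} -> "
                        f"{rec.label} (seed {params.seed}); "
                        f"{len(reverts)} reverts already used")
                depth = min(1 + block_fail // 2, len(ckpts))
                g_s, g_pos, g_vel, g_tether, g_sign = ckpts[-depth]
                del ckpts[len(ckpts) - depth + 1:]
                reverts.append(step)
                state.positions[:] = g_pos
                state.velocities[:] = g_vel
                state.tether_index = g_tether
                state.force_sign = g_sign
                seed(params.seed + 7919 * len(reverts))
                s = g_s + 1
                continue
            block_fail = 0
            records[s] = rec
            _record(s, step)
            if not state.circular and flip_rule(rec, state, protocol):
                flips.append(step)
            ckpts.append((s, state.positions.copy(), state.velocities.copy(),
                          state.tether_index, state.force_sign))
            if len(ckpts) > 16:
                ckpts.pop(0)
        else:
            _record(s, step)
        s += 1
    meta = {
        "reverts": reverts,
        "protocol": protocol.to_dict(),
        "langevin": params.to_dict(),
        "forcefield": ff.to_dict(),
        "seed": params.seed,
        "circular": state.circular,
        "knot_label": ref_label,
        "flips": flips,
        "channel": None if channel is None else channel.spec.to_dict(),
    }
    return Trajectory(times, frames, signs, records, meta)
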