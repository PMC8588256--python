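"""Shared fixtures: scaled-down production runs reused across test modules.

The full study protocol (5 replicas x 5e6 steps per condition) is scaled
down to single-replica runs of 6e5-2e6 steps so the whole suite stays
within an ordinary CI budget; the statistical assertions account for the
larger sampling error this implies.  Expensive channel insertions are
performed once per condition and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from helknot.channel import HelicalChannelSpec
from helknot.dynamics import LangevinParams, ProtocolConfig, run_protocol
from helknot.forcefield import ForceFieldParams
from helknot.knot_factory import (
    generate_knot,
    make_knotoid,
    insert_chain_into_channel,
)
from helknot.transport import DriftSeries, analyze_transport

#: default helical channel of the confined-trefoil study (left-handed)
CHANNEL = HelicalChannelSpec(r_ch=3.0, r_h=1.5, pitch_k=1.5,
                             handedness=-1, n_turns=12)


@pytest.fixture(scope="session")
def trefoil_knotoid():
    """<+>3_1 knotoid on a 100-bead chain (writhe-positive trefoil)."""
    ring = generate_knot("3_1", 100, chirality=+1)
    return make_knotoid(ring, seed=11)


@pytest.fixture(scope="session")
def free_space_run(trefoil_knotoid):
    """Scaled free-space pulling run: 1 replica, 5e5 steps, 100 beads."""
    proto = ProtocolConfig(total_steps=500_000, sample_every=1000,
                           n_replicas=1)
    return run_protocol(trefoil_knotoid, None, proto, LangevinParams(seed=21))


def _inserted_state(label, chirality, channel, seed, n_beads=100):
    if channel.periodic:
        ring = generate_knot(label, n_beads, chirality=chirality)
        return insert_chain_into_channel(ring, channel, rng_seed=seed)
    ring = generate_knot(label, n_beads, chirality=chirality)
    kn = make_knotoid(ring, seed=11)
    st, geom = insert_chain_into_channel(kn, channel, rng_seed=seed)
    st.tether_index = 0
    st.force_sign = 1
    return st, geom


@pytest.fixture(scope="session")
def inserted_trefoil_plus():
    """<+>3_1 confined in the left-handed helix: the ANTICHIRAL setup."""
    return _inserted_state("3_1", +1, CHANNEL, 31)


@pytest.fixture(scope="session")
def inserted_trefoil_minus():
    """<->3_1 confined in the left-handed helix: the EQUICHIRAL setup."""
    return _inserted_state("3_1", -1, CHANNEL, 31)


def _run(state_geom, total_steps, seed, f_ext=None):
    st, geom = state_geom
    proto = ProtocolConfig(total_steps=total_steps, sample_every=1000,
                           n_replicas=1)
    ff = ForceFieldParams() if f_ext is None else ForceFieldParams(f_ext=f_ext)
    return run_protocol(st, geom, proto, LangevinParams(seed=seed), ff=ff)


@pytest.fixture(scope="session")
def confined_antichiral(inserted_trefoil_plus):
    return _run(inserted_trefoil_plus, 2_000_000, 41)


@pytest.fixture(scope="session")
def confined_equichiral(inserted_trefoil_minus):
    return _run(inserted_trefoil_minus, 2_000_000, 41)


@pytest.fixture(scope="session")
def transport_pair(confined_antichiral, confined_equichiral):
    out = {}
    for name, traj in (("antichiral", confined_antichiral),
                       ("equichiral", confined_equichiral)):
        series = DriftSeries.from_trajectory(traj)
        out[name] = analyze_transport([series])
    return out


@pytest.fixture(scope="session")
def zero_force_pair(inserted_trefoil_plus, inserted_trefoil_minus):
    """Confined trefoils with the pull switched off (diffusion only)."""
    out = {}
    for name, sg in (("antichiral", inserted_trefoil_plus),
                     ("equichiral", inserted_trefoil_minus)):
        traj = _run(sg, 600_000, 43, f_ext=0.0)
        series = DriftSeries.from_trajectory(traj)
        out[name] = analyze_transport([series], f_ext=0.0)
    return out


@pytest.fixture(scope="session")
def achiral_pair():
    """4_1 knotoid driven through both channel handednesses."""
    out = {}
    for name, hand in (("left", -1), ("right", +1)):
        channel = HelicalChannelSpec(r_ch=3.0, r_h=1.5, pitch_k=1.5,
                                     handedness=hand, n_turns=12)
        sg = _inserted_state("4_1", 0, channel, 33)
        traj = _run(sg, 600_000, 45)
        series = DriftSeries.from_trajectory(traj)
        out[name] = analyze_transport([series])
    return out


@pytest.fixture(scope="session")
def circular_pair():
    """75-bead circular trefoils in a periodic right-handed helix."""
    from helknot.units import DEFAULT_UNITS as U

    channel = HelicalChannelSpec(r_ch=3.0, r_h=1.0, pitch_k=1.5,
                                 handedness=+1, n_turns=8, periodic=True)
    out = {}
    for name, chir in (("equichiral", +1), ("antichiral", -1)):
        sg = _inserted_state("3_1", chir, channel, 7, n_beads=75)
        traj = _run(sg, 600_000, 47)
        com_z = traj.positions.mean(axis=1)[:, 2]
        series = DriftSeries(U.convert(traj.times, "time") * 1e-9,
                             com_z * U.sigma_nm, traj.force_signs)
        out[name] = analyze_transport([series])
    return out
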