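# helknot

Coarse-grained Langevin simulation of knotted DNA-like chains driven
through helically modulated nanochannels, with a full knot-topology
detection stack and drift/diffusivity analysis.

## The problem

A knot tied on a DNA molecule is a *chiral* object: the trefoil 3_1 exists
as left- and right-handed enantiomers distinguished by the sign of their
writhe, and no ordinary channel or force can tell them apart.  A channel
whose wall is itself helically modulated breaks that symmetry.  `helknot`
reproduces the computational experiment demonstrating this: a bead-spring
DNA model (1 bead = 10 bp = 3 nm, persistence length 45 nm, WCA excluded
volume, harmonic bonds and bending) is pulled by a per-bead force
`F_ext = 0.05 eps0/sigma = 0.07 pN` through an explicit bead-built helical
tube of radius `R_ch`, helix radius `R_H` and pitch `2 pi k`.  When the
knot's writhe sign matches the channel handedness (*equichiral*) the knot
slides through; when it opposes it (*antichiral*) the knot arc gets caught
in the helical grooves and both its drift speed `v_drift` and diffusivity
`D` collapse — a stereospecific filter for knot chirality.  Amphichiral
knots (4_1, 6_3, 8_18) feel nothing; for knots on circular chains the
effect inverts.

Knot identification runs continuously during the dynamics: KMT chain
reduction, closure (at infinity along the stretching axis, or
out-and-around), Alexander invariants |Delta(-1)|, |Delta(-2)| computed
exactly by modular interpolation, knot-core localization, and Gauss-sum
writhe for the chirality sign.

Audience: polymer physicists and nanofluidics people who want a
self-contained, fully scripted re-implementation of the stereoselective
transport experiment, or just a compact knot-analysis toolkit for bead
chains.

## Worked example

```python
import numpy as np
from helknot.channel import HelicalChannelSpec
from helknot.dynamics import LangevinParams, ProtocolConfig, run_protocol
from helknot.knot_factory import (generate_knot, make_knotoid,
                                  insert_chain_into_channel)
from helknot.transport import DriftSeries, analyze_transport

channel = HelicalChannelSpec(r_ch=3.0, r_h=1.5, pitch_k=1.5,
                             handedness=-1, n_turns=12)
proto = ProtocolConfig(total_steps=1_000_000, sample_every=1000, n_replicas=1)

for name, chirality in (("antichiral", +1), ("equichiral", -1)):
    ring = generate_knot("3_1", 100, chirality=chirality)   # writhe sign
    knotoid = make_knotoid(ring, seed=11)                   # cut + pre-stretch
    state, geom = insert_chain_into_channel(knotoid, channel, rng_seed=31)
    state.tether_index, state.force_sign = 0, 1
    traj = run_protocol(state, geom, proto, LangevinParams(seed=41))
    res = analyze_transport([DriftSeries.from_trajectory(traj)])
    print(name, res.summary())
```

Output from this exact script (single replicas, so a few percent of
sampling scatter on re-seeding):

```
antichiral v_drift = 158.3 +- 0.4 um/s; D = 1.41 +- 0.03 um^2/s (R^2 = 0.9693, drift_fit+msd_ballistic)
equichiral v_drift = 601.1 +- 1.4 um/s; D = 9.48 +- 0.21 um^2/s (R^2 = 0.9811, drift_fit+msd_ballistic)
```

The equichiral trefoil drifts ~4x faster and diffuses ~7x faster than its
mirror image in the same left-handed channel — the channel reads the
knot's handedness.  Swapping both the knot chirality and the channel
handedness leaves the numbers statistically unchanged (mirror symmetry);
driving the amphichiral 4_1 through either channel gives a ratio
compatible with 1.

There is also a thin CLI (`helknot build-channel`, `make-knot`,
`simulate`, `analyze-topology`, `analyze-transport`, `sweep`) over the
same library calls; `helknot simulate config.yaml` runs a scenario from a
YAML config.

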