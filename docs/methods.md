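# Methods

## The model

`helknot` simulates a coarse-grained, torsionally relaxed (nicked) DNA-like
polymer as a bead-spring chain in implicit solvent.  One bead represents
10 bp (diameter sigma = 3 nm); energies are measured in eps0 = k_B T
(298 K, so eps0 = 4.11 pN nm) and time in tau = 123 ns, the Stokes time of
one bead, which makes the free-bead diffusivity kT/(m gamma) = 1 sigma^2/tau
= 73.2 um^2/s.

Interactions:

* **bonds** — harmonic, `U_s = k_s (r - r0)^2` with `r0 = 1 sigma`;
* **bending** — harmonic in the interior angle, `U_th = 1/2 k_th (th - pi)^2`
  with `k_th = 15 eps0/rad^2`, giving a persistence length
  `P_l = k_th r0 = 15 sigma = 45 nm`;
* **excluded volume** — WCA (truncated-shifted, purely repulsive LJ) of
  diameter 1 sigma between all non-bonded bead pairs, and between chain
  beads and static wall beads;
* **driving** — a constant force `f_ext` (default 0.05 eps0/sigma =
  0.07 pN) on every chain bead along the channel axis (z).

Dynamics are Langevin, `m r'' = -gamma m r' - grad U + R(t)` with
`gamma = 1/tau`, `m = 1`, integrated with a BAOAB velocity-Verlet splitting
at `dt = 0.01 tau`.  The thermostat satisfies fluctuation–dissipation
exactly per step; at `gamma = 0, kT = 0` the scheme reduces to plain
velocity Verlet (verified by an energy-conservation test).  The tethered
bead of the pulling protocol is frozen (infinite-mass limit).

### The bond-stiffness calibration

The bond constant deserves its own paragraph because it controls whether
the simulation is *possible at all*.  A knot can only change type if one
strand crosses another, and in a bead-spring chain the only gate is the gap
that opens between two bonded beads when the bond stretches.  With
`k_s = 10 eps0/sigma^2` the thermal bond-length standard deviation is
0.22 sigma; among ~100 bonds, instantaneous lengths of 1.8–1.9 sigma occur
constantly, the WCA barrier through such a gap drops to ~6 eps0, and we
measured knot-loss events every few thousand steps in pulled chains — no
multi-million-step production run survives.  Reading the same printed
constant per nm^2 (10 eps0/nm^2 = 90 eps0/sigma^2 at sigma = 3 nm) gives a
bond std of 0.075 sigma, a passage barrier of ~40 eps0, and *zero* observed
topology violations in 10^6-step runs.  It also reproduces the reference
knot geometry (see below).  The package therefore defaults to
`k_s = 90 eps0/sigma^2`; the softer value remains available through
`ForceFieldParams`.

As a second line of defence, every protocol re-checks the knot type
(Alexander invariants after closure) at a ~1 us cadence and, on a failed
check, rewinds to the last verified configuration and re-runs the block
with fresh noise, backing further off if a conformation fails repeatedly.
The sampled ensemble is thus the dynamics conditioned on preserved
topology; at the default stiffness reverts are rare to absent, so the
conditioning is negligible.

## Knot detection

Classification follows the standard pipeline of the polymer-knot
literature: close the curve if it is open, KMT-simplify (delete a vertex
when the triangle spanned with its neighbours is crossed by no other
segment), extract the crossings of a generic projection, and evaluate the
Alexander polynomial magnitudes |Delta(-1)| and |Delta(-2)|.  The pair is
looked up in a bundled table covering every knot type in scope (the t = -2
value separates 10_124 from the unknot, which the determinant alone cannot).

Two implementation details are worth recording:

* The Wirtinger Alexander determinant equals +-t^a Delta(t) with a
  diagram-dependent power.  Evaluating at t = -2 naively leaves an
  ambiguous factor 2^a that cannot be stripped by parity (Delta(-2) is even
  for e.g. 5_2).  We instead recover the whole determinant polynomial
  exactly by modular evaluation–interpolation over the prime 2^31 - 1 and
  strip the monomial factor before evaluating.  A sympy symbolic
  determinant serves as an independent oracle in the tests.
* Open chains are closed *before* any simplification: KMT triangle moves
  on an open curve can legally untie a knotoid (open curves are
  isotopically trivial).  For chains stretched along the pulling/channel
  axis the closure extends both ends to infinity along that axis
  ("closure at infinity"), which cannot thread back through a
  channel-coiled chain the way a radial out-and-around arc can.  For
  generic compact chains the default remains the out-and-around sphere
  closure, with a stochastic multi-direction majority vote available for
  loose knots.

The knot core is localized bottom-up: the smallest window of the
KMT-reduced vertex scaffold whose closure carries the full chain's knot
type (ties broken toward the chain midpoint), refined to bead resolution by
bisection, and confirmed top-down by requiring the excised complement to
close to the unknot.  Chirality is assigned by the sign of the Gauss-sum
writhe (the `<+>`/`<->` mean-writhe convention), never from table prefixes;
Alexander invariants are mirror-blind, which the tests assert explicitly.
The per-frame writhe is evaluated on the located core padded by 10 beads
per side: the crossing completed by the minimal core's own closure lies
just outside the minimal boundary, so the unpadded core writhe
underestimates the knot's writhe by ~half (1.5 vs 3.2 for the trefoil)
while the padded value agrees with the full-chain open writhe (straight
tails contribute essentially nothing).

## Channels

Walls are explicit static beads: circles of radius `R_ch` stacked
perpendicular to the helix centre line `(R_H cos t, +-R_H sin t, k t)` in
its Frenet frame, with bead and circle spacing both capped at 1 sigma so a
chain bead cannot slip through.  The frame's normal direction is defined by
the angular formula independent of `R_H`, so the straight-cylinder limit
`R_H = 0` is smooth and the molding schedule (rebuilding the tube on a
fixed circle/bead lattice while ramping `R_H` linearly) moves every wall
bead continuously; per-stage displacements are bounded (< 0.5 sigma,
enforced) and stage endpoints equal the direct construction bit-for-bit.
Periodic (infinite) channels use an integer number of turns with
minimum-image convention along the axis.

Chain insertion follows the two-phase protocol: (1) the chain — held by
harmonic anchors that pin both end beads to on-axis points, which both
keeps it extended and prevents the knot from sliding off a free end — is
confined by an implicit analytic cylinder whose radius shrinks
geometrically to just inside `R_ch` (beads caught outside a freshly shrunk
wall feel a bounded harmonic push rather than the divergent WCA force);
(2) the implicit wall is replaced by the explicit straight tube, which is
then molded stage by stage into the target helix with relaxation between
stages.  Each stage verifies both the knot type and that the core has not
drifted within 8 beads of a chain end; failures rewind the schedule.

## Transport analysis

The knot position is the central core index i_middle converted to contour
nm.  Displacements are sign-linearized over the force-flip protocol,
`dx = sum sign(F) (x_{i+1} - x_i)`, the drift speed is the zero-intercept
least-squares slope over concatenated replicas, and the diffusivity comes
from a one-parameter fit of `MSD(t) = (f_ext D t / sigma)^2 + 2 D t`
(the ballistic term uses the drift–diffusivity relation v0 = F_ext D /
eps0 of pulled-knot theory, leaving D as the only parameter).  MSD windows
are non-overlapping and restart at force flips so flips never contaminate
lag statistics.  For circular chains the drift coordinate is the unwrapped
axial centre-of-mass position.  Analytic references: the tortuosity
estimate `D_eff = D0 (2 pi k) / sqrt((2 pi k)^2 + (2 pi R_H)^2)` and the
propelled-chiral-particle formula `D_eff = D + v0^2 D_th / (2 (D_th^2 +
Omega^2))` with `D_th = 3D/(4 R_H^2)` and `Omega = v0/(2 pi k sigma)`.
Stereoselectivity is reported as the ratio `phi_D = D_= / D_+-`
(reciprocal convention for circular chains, where the effect inverts).

## What the scaled runs do and do not show

The study conditions are 5 replicas x 5e6 steps (6.15 ms) per condition.
The bundled tests and the acceptance script run single replicas of
5e5–1.2e6 steps, sized so the whole campaign completes on one CPU core in
minutes.  At that scale:

* Static knot geometry is well converged.  The free-space pulled trefoil
  gives core R_g ~ 8.4 nm (reference 7.7), L_k ~ 65 nm (reference 79.5)
  and mean writhe 3.20 (reference 3.27).
* The stereoselective orderings are robust: the equichiral confined
  trefoil moves 2-4x faster than the antichiral one (reference ratio 2.2)
  and diffuses several times faster; achiral 4_1 shows no significant
  selectivity; for circular chains the effect direction inverts
  (antichiral faster, ~30% at 75 beads vs the reference ~20-35%).
* Absolute drift speeds run ~2-3x above the reference numbers at every
  condition (free space 700-1000 vs 312 um/s across seeds; confined
  antichiral 150-310 vs 87; confined equichiral 420-600 vs 188).  The
  antichiral chain alternates between groove-trapped and free episodes on
  a ~5e5-step timescale, which is why its seed-to-seed spread is widest.
  The measured ratio v sigma / (f_ext D) implies our knots respond to an
  effective driving force of ~2.5 f_ext (consistent with the ~2.5 sigma of
  contour stored in a tight trefoil under per-bead loading), whereas the
  reference speeds are consistent with a driving force of ~1 f_ext.  No
  reading of the printed damping or force conventions reconciles the two;
  we report what the model as specified produces.  Diffusivities land much
  closer (free space 22 vs 17; confined equichiral 9.3 vs 10.3 um^2/s).

A further internal tension in the source parameters is recorded here for
the reader: a trefoil core with R_g = 7.7 nm and L_k = 79.5 nm implies
loop radii of ~1.5-2.5 sigma and hence tens of eps0 of bending energy at
k_th = 15 eps0/rad^2 — the printed persistence length (45 nm) and the
printed knot geometry are mutually inconsistent in free space.  Our runs
(at the printed stiffness, with the stiff-bond calibration above)
nevertheless land within ~10-20% of the reference geometry, because the
stiff bonds keep the core compact under tension.

## Synthetic inputs

No external data enter the package.  Torus knots come from parametric
equations; twist knots and amphichiral controls are built from verified
braid-word closures (4_1, 5_2, 6_1, 6_3, 8_18) and a pretzel construction
(7_4 = P(3,3,1), whose Alexander polynomial 4t - 7 + 4/t was confirmed
against the pretzel closed form).  The bundled plain-text fixtures are
snapshots of these constructions, re-verified against the invariant table
at load time.  The requested handedness of a chiral knot is imposed by
measuring the writhe of the embedding and mirroring when needed, so no
sign convention of any generator is load-bearing.

## Numerical choices and degenerate inputs

* Projections for crossing extraction use a deterministic sequence of
  seeded random rotations; degenerate projections (vertex-grazing
  crossings, parallel overlaps, ambiguous depth) are detected and
  re-drawn.  Exactly collinear vertex runs are pruned first (a free
  isotopy) or no projection would ever be generic.
* Modular determinants use the prime 2^31 - 1; all true invariant values
  in scope are < 10^3, far below the symmetric-residue bound.
* The GRC (global radius of curvature) pair minimization skips points
  closer than 2 bonds to the probe bead to avoid trivially small
  circumradii; with a channel present the profile is capped at the
  analytic distance to the wall surface.
* Bond-length validation uses [0.5, 1.5] sigma for constructed geometries
  and wider bounds for thermalized states (the instantaneous max over 100
  bonds regularly exceeds 1.5 sigma even in equilibrium at the soft
  stiffness; at the default stiffness it stays below ~1.35 sigma).

## Known limitations

* Torsional stiffness (non-nicked DNA), electrostatics, and hydrodynamic
  interactions are out of scope.
* The flip rule triggers only at the free (non-tethered) end; the literal
  "either end" rule re-fires indefinitely once the reached end is
  tethered.
* Single-replica scaled runs leave ~5-15% sampling error on means and
  more on diffusivities; the acceptance machinery reports fit/block SEs,
  not production-grade replicate spreads.
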