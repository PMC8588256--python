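"""Generation of knotted bead-chain conformations.

Torus knots come from the standard parametric equations; the remaining knot
types (twist knots and the amphichiral controls) are built from braid-word
closures and pretzel diagrams, then uniformly resampled to 1-sigma bonds.
Every generated conformation is verified against the Alexander invariant
table before use, and the requested handedness is imposed by measuring the
writhe and mirroring if needed (chirality here is a property of the
embedding, not of the label).

The module also provides the knotoid preparation step (cut one bond, pull
both ends at 10 pN until the end-to-end distance plateaus, so the knot
localizes on the now-linear chain) and the two-phase protocol that places a
chain inside an explicitly modelled helical tube.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .topology import (
    classify_knot,
    writhe,
    TopologyError,
    AMPHICHIRAL,
)


class KnotGenerationError(RuntimeError):
    pass


@dataclass
class ChainState:
    """Bead chain: positions/velocities in reduced units.

    ``tether_index`` is the frozen bead of the pulling protocol (None for
    circular chains); ``force_sign`` multiplies the external force axis.
    """

    positions: np.ndarray
    velocities: np.ndarray
    circular: bool
    tether_index: int | None = None
    force_sign: int = 1

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bond_lengths(self) -> np.ndarray:
        p = self.positions
        if self.circular:
            d = np.roll(p, -1, axis=0) - p
        else:
            d = np.diff(p, axis=0)
        return np.linalg.norm(d, axis=1)

    def validate(self, strict: bool = True) -> None:
        """Check bond-length sanity.

        ``strict`` bounds [0.5, 1.5] sigma apply to freshly constructed
        geometries; thermalized states use wider bounds because with
        k_s = 10 eps0/sigma^2 the instantaneous bond-length std is
        ~0.22 sigma, so the largest of ~100 bonds regularly exceeds
        1.5 sigma in equilibrium.
        """
        b = self.bond_lengths()
        lo, hi = (0.5, 1.5) if strict else (0.35, 2.0)
        if b.min() < lo or b.max() > hi:
            raise KnotGenerationError(
                f"bond lengths out of [{lo}, {hi}] sigma: "
                f"min={b.min():.3f}, max={b.max():.3f}")
        if self.circular and self.tether_index is not None:
            raise KnotGenerationError("circular chains cannot be tethered")

    def copy(self) -> "ChainState":
        return ChainState(self.positions.copy(), self.velocities.copy(),
                          self.circular, self.tether_index, self.force_sign)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_equal_arclength(coords: np.ndarray, n_beads: int,
                             closed: bool) -> np.ndarray:
    """Resample a polyline to ``n_beads`` vertices with bond length 1 sigma.

    Iterates equal-arc-length resampling and rescaling until the summed
    chord (contour) length equals ``n_beads`` (closed) or ``n_beads - 1``
    (open) sigma to 1e-9.
    """
    pts = np.asarray(coords, dtype=float)
    target = float(n_beads if closed else n_beads - 1)
    for _ in range(12):
        if closed:
            ring = np.vstack([pts, pts[:1]])
        else:
            ring = pts
        seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        s_new = np.linspace(0.0, total, n_beads, endpoint=False) if closed \
            else np.linspace(0.0, total, n_beads)
        new = np.empty((n_beads, 3))
        for d in range(3):
            new[:, d] = np.interp(s_new, cum, ring[:, d])
        # rescale so the chord contour equals the target exactly
        if closed:
            chords = np.linalg.norm(np.roll(new, -1, axis=0) - new, axis=1)
        else:
            chords = np.linalg.norm(np.diff(new, axis=0), axis=1)
        scale = target / chords.sum()
        centroid = new.mean(axis=0)
        pts = (new - centroid) * scale + centroid * scale
        if abs(chords.sum() * scale - target) < 1e-10 and \
                abs(scale - 1.0) < 1e-10:
            break
    return pts


def _mirror(coords: np.ndarray) -> np.ndarray:
    out = np.asarray(coords, dtype=float).copy()
    out[:, 2] *= -1.0
    return out


def _impose_chirality(coords: np.ndarray, label: str, chirality: int,
                      closed: bool = True) -> np.ndarray:
    """Mirror the embedding if needed so sign(writhe) == chirality."""
    if label in AMPHICHIRAL or chirality == 0:
        return coords
    wr = writhe(coords, closed)
    if np.sign(wr) != np.sign(chirality):
        coords = _mirror(coords)
    return coords


# ---------------------------------------------------------------------------
# torus knots
# ---------------------------------------------------------------------------

def torus_knot_coords(p: int, q: int, n_beads: int = 100,
                      chirality: int = 0, verify: bool = True) -> ChainState:
    """Closed T(p, q) torus-knot chain with 1-sigma bonds.

    ``chirality`` = +1/-1 selects the enantiomer by writhe sign (0 keeps
    the raw parametric handedness).  gcd(p, q) must be 1 (else the curve is
    a link, not a knot).
    """
    if np.gcd(p, q) != 1:
        raise KnotGenerationError(f"T({p},{q}) is a link (gcd != 1), not a knot")
    dense = max(40 * max(abs(p), abs(q)), 200)
    t = np.linspace(0, 2 * np.pi, dense, endpoint=False)
    r = 2.0 + np.cos(p * t)
    pts = np.column_stack([r * np.cos(q * t), r * np.sin(q * t), np.sin(p * t)])
    pts = resample_equal_arclength(pts, n_beads, closed=True)
    label = classify_knot(pts, closed=True)
    if chirality:
        pts = _impose_chirality(pts, label, chirality)
    if verify:
        expected = _torus_label(p, q)
        if expected is not None and label != expected:
            raise KnotGenerationError(
                f"T({p},{q}) generated as {label}, expected {expected}; "
                f"raise n_beads (resampling too coarse)")
    state = ChainState(pts, np.zeros_like(pts), circular=True)
    state.validate()
    return state


def _torus_label(p: int, q: int) -> str | None:
    key = tuple(sorted((abs(p), abs(q))))
    return {(1, 1): "unknot", (2, 3): "3_1", (2, 5): "5_1",
            (2, 7): "7_1", (3, 5): "10_124"}.get(key)


# ---------------------------------------------------------------------------
# braid closures
# ---------------------------------------------------------------------------

def braid_closure_coords(word: list[int], n_strands: int,
                         n_beads: int = 100) -> ChainState:
    """Closed chain realizing the closure of a braid word.

    Letters +-j are sigma_j / sigma_j^-1 on strands j, j+1 (1-based).  The
    closure must be a single component or a :class:`KnotGenerationError` is
    raised.  Strands run down the z axis; over/under passes are realized by
    y-offsets and closure arcs are routed at distinct negative-y depths so
    the embedding is guaranteed.
    """
    # occupant[pos] = strand (labelled by its top position) currently at pos
    occupant = {k: k for k in range(1, n_strands + 1)}
    strand_paths = {k: [np.array([float(k), 0.0, 0.0])]
                    for k in range(1, n_strands + 1)}
    z = 0.0
    for letter in word:
        j = abs(letter)
        if not (1 <= j < n_strands):
            raise KnotGenerationError(f"braid letter {letter} out of range")
        z -= 2.0
        sa = occupant[j]        # strand at position j
        sb = occupant[j + 1]    # strand at position j+1
        # positive letter: strand at position j crosses OVER to position j+1
        ya, yb = (0.6, -0.6) if letter > 0 else (-0.6, 0.6)
        strand_paths[sa].append(np.array([j + 0.5, ya, z + 1.0]))
        strand_paths[sa].append(np.array([float(j + 1), 0.0, z]))
        strand_paths[sb].append(np.array([j + 0.5, yb, z + 1.0]))
        strand_paths[sb].append(np.array([float(j), 0.0, z]))
        occupant[j], occupant[j + 1] = sb, sa
        for k in range(1, n_strands + 1):
            if k not in (j, j + 1):
                strand_paths[occupant[k]].append(np.array([float(k), 0.0, z]))
    z_bot = z - 1.0
    for k in range(1, n_strands + 1):
        strand_paths[occupant[k]].append(np.array([float(k), 0.0, z_bot]))
    # closure: bottom position k loops around (at depth y = -(1+k)) to top k
    perm = {k: occupant[k] for k in range(1, n_strands + 1)}
    # walk components: strand s starts at top position s and ends at bottom
    # position p where perm[p] == s
    end_pos = {v: k for k, v in perm.items()}
    visited = set()
    comp = []
    pos = 1
    while True:
        s = pos  # strand starting at top position pos
        if s in visited:
            break
        visited.add(s)
        comp.append(s)
        pos = end_pos[s]  # bottom position where this strand ends = next top
    if len(visited) != n_strands:
        raise KnotGenerationError(
            f"braid closure has {len(set(visited))}+ components; not a knot")
    pts = []
    for s in comp:
        pts.extend(strand_paths[s])
        # closure arc from bottom position end_pos[s] to top position end_pos[s]
        k = end_pos[s]
        depth = -(1.5 + 0.7 * k)
        pts.append(np.array([float(k), depth, z_bot]))
        pts.append(np.array([float(k), depth, 1.0]))
        pts.append(np.array([float(k), 0.0, 1.0]))
        # continue at top position k (= start of next strand in comp)
    pts = np.array(pts)
    pts = resample_equal_arclength(_densify(pts, 0.5), n_beads, closed=True)
    state = ChainState(pts, np.zeros_like(pts), circular=True)
    state.validate()
    return state


def _densify(pts: np.ndarray, max_seg: float) -> np.ndarray:
    """Insert vertices so no segment exceeds ``max_seg`` (keeps shape)."""
    out = []
    n = len(pts)
    for i in range(n):
        a = pts[i]
        b = pts[(i + 1) % n]
        out.append(a)
        d = np.linalg.norm(b - a)
        for kk in range(1, int(np.ceil(d / max_seg))):
            out.append(a + (b - a) * kk / np.ceil(d / max_seg))
    return np.array(out)


# ---------------------------------------------------------------------------
# pretzel knots
# ---------------------------------------------------------------------------

def pretzel_coords(p: int, q: int, r: int, n_beads: int = 100) -> ChainState:
    """Closed chain realizing the (p, q, r) pretzel knot (all odd).

    Three vertical two-strand bands with p, q, r signed half-twists,
    connected by top and bottom bars; e.g. (1,1,1) -> trefoil,
    (3,3,1) -> 7_4.
    """
    twists = (p, q, r)
    if any(abs(t) % 2 == 0 for t in twists):
        raise KnotGenerationError("pretzel builder requires odd twist counts")
    H = 6.0
    band_x = [0.0, 4.0, 8.0]
    rad = 0.8
    strands = []  # per band: (left polyline bottom->top, right polyline)
    for bx, tw in zip(band_x, twists):
        nseg = 12 * abs(tw)
        zz = np.linspace(0.0, H, nseg)
        phi = np.pi * tw * zz / H
        a = np.column_stack([bx + rad * np.cos(phi), rad * np.sin(phi), zz])
        b = np.column_stack([bx - rad * np.cos(phi), -rad * np.sin(phi), zz])
        strands.append((a, b))
    # endpoints: band i bottom-left/right = strand start sorted by x
    def ends(i, top):
        a, b = strands[i]
        pa = a[-1] if top else a[0]
        pb = b[-1] if top else b[0]
        return (pa, pb) if pa[0] < pb[0] else (pb, pa)
    # walk the pretzel cycle explicitly; odd twists swap band sides, and the
    # diagram closes as: top: L1-outer, R1-L2, R2-L3, R3-outer;
    # bottom likewise. Build path by following connectivity.
    conn_z_top = H + 1.2
    conn_z_bot = -1.2
    outer_z_top = H + 2.4
    outer_z_bot = -2.4

    # Explicit walk over the diagram graph:
    # nodes: (band, side in {L,R}, end in {T,B}) ; connections:
    # T: (0,L)-outer-(2,R); (0,R)-(1,L); (1,R)-(2,L); B likewise.
    def conn(band, side, top):
        if top:
            if (band, side) == (0, "L"):
                return (2, "R", True, "outer")
            if (band, side) == (2, "R"):
                return (0, "L", True, "outer")
            if (band, side) == (0, "R"):
                return (1, "L", True, "inner")
            if (band, side) == (1, "L"):
                return (0, "R", True, "inner")
            if (band, side) == (1, "R"):
                return (2, "L", True, "inner")
            if (band, side) == (2, "L"):
                return (1, "R", True, "inner")
        else:
            if (band, side) == (0, "L"):
                return (2, "R", False, "outer")
            if (band, side) == (2, "R"):
                return (0, "L", False, "outer")
            if (band, side) == (0, "R"):
                return (1, "L", False, "inner")
            if (band, side) == (1, "L"):
                return (0, "R", False, "inner")
            if (band, side) == (1, "R"):
                return (2, "L", False, "inner")
            if (band, side) == (2, "L"):
                return (1, "R", False, "inner")
        raise AssertionError

    def endpoint(band, side, top):
        lo, hi = ends(band, top)
        return lo if side == "L" else hi

    def side_of(band, pt, top):
        lo, hi = ends(band, top)
        return "L" if np.allclose(pt, lo) else "R"

    path = []
    band, side, top = 0, "L", False  # enter band0 at bottom-left, go up
    for _ in range(6):  # 3 bands x 2 traversals max
        # traverse band from (band, side, top) to the other end
        a, b = strands[band]
        entry = endpoint(band, side, top)
        # find the strand with this endpoint at the entry end
        for s in (a, b):
            pt = s[-1] if top else s[0]
            if np.allclose(pt, entry):
                seg = s[::-1] if top else s
                break
        path.extend(seg)
        exit_top = not top
        exit_pt = seg[-1]
        exit_side = side_of(band, exit_pt, exit_top)
        # connection to the next band
        nband, nside, ntop, kind = conn(band, exit_side, exit_top)
        npt = endpoint(nband, nside, ntop)
        if kind == "inner":
            zlev = conn_z_top if exit_top else conn_z_bot
            path.append(np.array([exit_pt[0], exit_pt[1], zlev]))
            path.append(np.array([npt[0], npt[1], zlev]))
        else:  # outer arc: route above/below everything at y pushed out
            zlev = outer_z_top if exit_top else outer_z_bot
            path.append(np.array([exit_pt[0], exit_pt[1], zlev]))
            path.append(np.array([npt[0], npt[1], zlev]))
        band, side, top = nband, nside, ntop
        if (band, side, top) == (0, "L", False):
            break
    pts = resample_equal_arclength(_densify(np.array(path), 0.5),
                                   n_beads, closed=True)
    state = ChainState(pts, np.zeros_like(pts), circular=True)
    state.validate()
    return state


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

#: How each supported knot type is constructed.  Braid words verified against
#: the Alexander invariant table at generation time.
KNOT_CATALOG: dict[str, dict] = {
    "unknot": {"torus": (1, 1)},
    "3_1": {"torus": (3, 2)},
    "5_1": {"torus": (5, 2)},
    "7_1": {"torus": (7, 2)},
    "10_124": {"torus": (3, 5)},
    "4_1": {"braid": ([1, -2, 1, -2], 3)},
    "5_2": {"braid": ([1, 1, 1, 2, -1, 2], 3)},
    "6_1": {"braid": ([1, 1, 2, -1, -3, 2, -3], 4)},
    "6_3": {"braid": ([1, 1, -2, 1, -2, -2], 3)},
    "7_4": {"pretzel": (3, 3, 1)},
    "8_18": {"braid": ([1, -2, 1, -2, 1, -2, 1, -2], 3)},
}


def generate_knot(label: str, n_beads: int = 100,
                  chirality: int = 0) -> ChainState:
    """Closed chain of the requested knot type and handedness.

    The generated conformation is classified before return; a mismatch
    raises (resampling too coarse or a bad catalog entry).
    """
    if label not in KNOT_CATALOG:
        raise KnotGenerationError(
            f"unknown knot label {label!r}; available: {sorted(KNOT_CATALOG)}")
    entry = KNOT_CATALOG[label]
    if "torus" in entry:
        p, q = entry["torus"]
        state = torus_knot_coords(p, q, n_beads, chirality=chirality,
                                  verify=False)
    elif "braid" in entry:
        word, ns = entry["braid"]
        state = braid_closure_coords(word, ns, n_beads)
    else:
        state = pretzel_coords(*entry["pretzel"], n_beads=n_beads)
    got = classify_knot(state.positions, closed=True)
    if got != label:
        raise KnotGenerationError(
            f"generator for {label} produced {got}; raise n_beads")
    if chirality:
        state.positions = _impose_chirality(state.positions, label, chirality)
    return state


# ---------------------------------------------------------------------------
# knotoid preparation (cut + pre-stretch)
# ---------------------------------------------------------------------------

def make_knotoid(chain: ChainState, stretch_force_pN: float = 10.0,
                 units=None, ff=None, langevin=None,
                 max_retries: int = 4, seed: int = 1234,
                 plateau_steps: int = 10_000,
                 max_stretch_steps: int = 400_000) -> ChainState:
    """Cut one bond of a knotted ring and pre-stretch into a knotoid.

    The chain is relaxed under +-``stretch_force_pN`` end forces (along z)
    until the end-to-end distance plateaus (< 1% relative change over
    ``plateau_steps`` steps), which localizes the knot on the now-linear
    chain.  Topology is verified (out-and-around closure) and the cut is
    retried at a different bond if the knot is lost while stretching.
    """
    from .units import DEFAULT_UNITS
    from .forcefield import ForceFieldParams
    from . import dynamics as dyn

    if not chain.circular:
        raise KnotGenerationError("make_knotoid needs a circular chain")
    units = units or DEFAULT_UNITS
    ff = ff or ForceFieldParams()
    langevin = langevin or dyn.LangevinParams(seed=seed)
    label = classify_knot(chain.positions, closed=True)
    f_end = units.to_reduced(stretch_force_pN, "force")
    n = chain.n_beads
    rng = np.random.default_rng(seed)
    cut = 0
    for attempt in range(max_retries):
        pts = np.roll(chain.positions, -(cut + 1), axis=0).copy()
        # the bond between the (old) cut and cut+1 beads is now the open end
        state = ChainState(pts, np.zeros_like(pts), circular=False,
                           tether_index=None, force_sign=1)
        dyn.seed(seed + 1000 * attempt)
        prev_ee = np.linalg.norm(state.positions[-1] - state.positions[0])
        ok = True
        steps_done = 0
        plateaus = 0
        reverts = 0
        chunk = max(plateau_steps // 4, 1000)
        # Ramp the end force up so the knot tightens and localizes before
        # the chain is taut.  Near the full nominal tension the harmonic
        # bonds of this discretisation stretch far enough (> 1.5 sigma)
        # that strand passages become likely, so each chunk is
        # checkpointed: on a failed topology check the state reverts and
        # the force ceiling backs off.  The knot still pre-localizes; the
        # production pulling protocol maintains localization afterwards.
        checkpoint = state.positions.copy(), state.velocities.copy()
        f_cap = 1.0
        while ok and steps_done < max_stretch_steps:
            frac = min(min(1.0, 0.15 + steps_done / (8 * plateau_steps)),
                       f_cap)
            dyn.langevin_step(state, langevin, ff, None,
                              n_steps=chunk, f_end=frac * f_end)
            steps_done += chunk
            lbl = classify_knot(state.positions, closed=False,
                                closure="axis")
            if lbl != label:
                reverts += 1
                if reverts > 30:
                    ok = False
                    break
                state.positions[:] = checkpoint[0]
                state.velocities[:] = checkpoint[1]
                f_cap = max(0.25, 0.85 * frac)
                dyn.seed(seed + 1000 * attempt + 7 * reverts)
                continue
            checkpoint = state.positions.copy(), state.velocities.copy()
            if frac < f_cap and steps_done < 8 * plateau_steps:
                continue
            ee = np.linalg.norm(state.positions[-1] - state.positions[0])
            if abs(ee - prev_ee) < 0.01 * max(ee, 1.0):
                plateaus += 1
                if plateaus >= 2:
                    break
            else:
                plateaus = 0
            prev_ee = ee
        if ok and classify_knot(state.positions, closed=False,
                                closure="axis") == label:
            # release the tension briefly so bonds return to ~1 sigma
            dyn.langevin_step(state, langevin, ff, None,
                              n_steps=plateau_steps // 2, f_end=0.0)
            if classify_knot(state.positions, closed=False,
                             closure="axis") != label:
                cut = int(rng.integers(0, n))
                continue
            # require a reasonably centred core: a knot sitting at a chain
            # end slides off during the subsequent confinement protocol
            # (an unknotted ring has no core; it just becomes a linear chain)
            if label != "unknot":
                from .topology import locate_knot_core

                core = locate_knot_core(state.positions, closure="axis")
                if core is None or core[0] < n // 4 or core[1] > n - n // 4:
                    cut = int(rng.integers(0, n))
                    continue
            # orient: bead 0 at low z, tether it, force pushes the knot up
            if state.positions[0, 2] > state.positions[-1, 2]:
                state.positions = state.positions[::-1].copy()
                state.velocities = state.velocities[::-1].copy()
            state.tether_index = 0
            state.force_sign = 1
            state.velocities[:] = 0.0
            state.validate(strict=False)
            return state
        cut = int(rng.integers(0, n))
    raise KnotGenerationError(
        f"knot {label} lost during pre-stretch after {max_retries} cuts")


# ---------------------------------------------------------------------------
# channel insertion (two-phase protocol)
# ---------------------------------------------------------------------------

def insert_chain_into_channel(chain: ChainState, target,
                              rng_seed: int = 99,
                              ff=None, langevin=None,
                              n_mold_stages: int = 40,
                              shrink_stages: int = 15,
                              relax_steps: int = 4000,
                              margin: float = 8.0,
                              max_attempts: int = 3):
    """Confine a chain in a helical tube; returns (state, ChannelGeometry).

    Phase 1: the chain (stretched along z for linear chains) is confined by
    an implicit cylinder whose radius shrinks stepwise from well above the
    chain's radial extent down to just inside the tube radius, with
    relaxation and topology checks at every stage.  Phase 2: the implicit
    wall is replaced by an explicit straight bead tube, which is then
    molded stage by stage into the target helix.  A protocol attempt whose
    stage reverts keep failing (the knot trapped against a chain end) is
    abandoned and restarted with a shifted seed.
    """
    last = None
    for attempt in range(max_attempts):
        try:
            return _insert_once(chain, target, rng_seed + 7777 * attempt,
                                ff, langevin, n_mold_stages, shrink_stages,
                                relax_steps, margin)
        except KnotGenerationError as exc:
            last = exc
    raise KnotGenerationError(
        f"channel insertion failed after {max_attempts} attempts: {last}")


def _insert_once(chain, target, rng_seed, ff, langevin, n_mold_stages,
                 shrink_stages, relax_steps, margin):
    from .forcefield import ForceFieldParams
    from . import dynamics as dyn
    from .channel import build_helical_tube, mold_to_helix
    from dataclasses import replace as dc_replace

    ff = ff or ForceFieldParams()
    langevin = langevin or dyn.LangevinParams(seed=rng_seed)
    state = chain.copy()
    state.tether_index = None     # the end anchors hold the chain instead

    def _insertion_label(st):
        # linear chains are held stretched along z: close along the axis so
        # the closure cannot thread back through the channel-coiled chain
        if st.circular:
            return classify_knot(st.positions, closed=True)
        return classify_knot(st.positions, closed=False, closure="axis")

    def _stage_ok(st):
        """Knot type preserved AND (for linear chains) core not drifting
        off a chain end -- catching the drift early lets the revert undo
        it before the knot escapes."""
        if _insertion_label(st) != label:
            return False
        if st.circular or label == "unknot":
            return True
        from .topology import locate_knot_core

        try:
            core = locate_knot_core(st.positions, closure="axis")
        except TopologyError:
            return False
        n_b = st.n_beads
        return core is not None and core[0] >= 8 and core[1] <= n_b - 8

    label = _insertion_label(state)
    dyn.seed(rng_seed)
    # centre the chain on the z axis inside the channel length
    pts = state.positions
    pts[:, 0] -= pts[:, 0].mean()
    pts[:, 1] -= pts[:, 1].mean()
    zmin = pts[:, 2].min()
    extent = pts[:, 2].max() - zmin
    L = target.axial_length
    if extent + 2 * margin > L and not target.periodic:
        raise KnotGenerationError(
            f"channel too short: chain extent {extent:.0f} + margins > {L:.0f}")
    pts[:, 2] += (margin - zmin) if not target.periodic else \
        (L / 2 - zmin - extent / 2)
    # harmonic anchors hold both chain ends at on-axis points: the chain
    # stays extended, the ends are guided to the channel centre, and the
    # knot cannot slide off a free end while the wall closes in
    if state.circular:
        anchors = None
    else:
        a0 = np.array([0.0, 0.0, pts[0, 2]])
        a1 = np.array([0.0, 0.0, pts[-1, 2]])
        anchors = (3.0, a0, a1)
    # build the full stage schedule up front so a failed stage can rewind
    # several stages (a passage-prone conformation escapes by re-running
    # earlier stages with fresh noise, not just re-rolling the same block)
    rho = np.hypot(pts[:, 0], pts[:, 1]).max()
    r_start = max(rho + 2.0, target.r_ch + 2.0)
    r_stop = target.r_ch - 0.6
    straight_spec = dc_replace(target, r_h=0.0)
    tgt_geom = build_helical_tube(target)
    straight = build_helical_tube(straight_spec, n_circles=tgt_geom.n_circles)
    schedule: list[tuple[str, dict]] = []
    for k, r in enumerate(np.geomspace(r_start, r_stop, shrink_stages)):
        schedule.append((f"shrink-{k}", {"cyl": float(r),
                                         "steps": relax_steps}))
    schedule.append(("substitute", {"channel": straight,
                                    "steps": relax_steps}))
    if target.r_h > 0:
        for k, g in enumerate(mold_to_helix(straight, target, n_mold_stages)):
            schedule.append((f"mold-{k}", {"channel": g,
                                           "steps": max(relax_steps // 2,
                                                        1000)}))
        final = schedule[-1][1]["channel"]
    else:
        final = straight
    schedule.append(("final", {"channel": final, "steps": relax_steps}))

    # checkpoints[j] = verified state entering stage j
    checkpoints = [(state.positions.copy(), state.velocities.copy())]
    reverts = 0
    fails_here = 0
    i = 0
    while i < len(schedule):
        name, kw = schedule[i]
        ok = True
        try:
            dyn.langevin_step(state, langevin, ff, kw.get("channel"),
                              n_steps=kw["steps"],
                              cyl_radius=kw.get("cyl", 0.0),
                              anchors=anchors)
        except dyn.ProtocolError:
            ok = False   # integrator blow-up: treat like a failed stage
        if ok and _stage_ok(state):
            checkpoints.append((state.positions.copy(),
                                state.velocities.copy()))
            i += 1
            fails_here = 0
            continue
        reverts += 1
        fails_here += 1
        if reverts > 150:
            raise KnotGenerationError(
                f"topology repeatedly changed during insertion stage {name} "
                f"(seed {rng_seed}, {reverts} reverts)")
        i = max(i - fails_here, 0)
        checkpoints = checkpoints[:i + 1]
        state.positions[:] = checkpoints[i][0]
        state.velocities[:] = checkpoints[i][1]
        dyn.seed(rng_seed + 101 * reverts)
    state.velocities[:] = 0.0
    return state, final


# ---------------------------------------------------------------------------
# plain-text fixtures
# ---------------------------------------------------------------------------

def load_knot_fixture(name: str, n_beads: int = 100) -> ChainState:
    """Load a bundled coordinate fixture and resample to ``n_beads``.

    Fixtures are whitespace-separated x y z per line with ``#`` header
    comments; they are synthetic conformations produced by this package's
    own generators.  Topology is verified after resampling.
    """
    fname = f"{name}.txt"
    try:
        text = (resources.files("helknot") / "data" / fname).read_text()
    except FileNotFoundError as exc:
        raise KnotGenerationError(f"no bundled fixture {fname}") from exc
    rows = [line.split() for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")]
    pts = np.array(rows, dtype=float)
    pts = resample_equal_arclength(pts, n_beads, closed=True)
    got = classify_knot(pts, closed=True)
    if got != name:
        raise KnotGenerationError(
            f"fixture {name} resampled to {n_beads} beads classifies as "
            f"{got}; raise n_beads")
    state = ChainState(pts, np.zeros_like(pts), circular=True)
    state.validate()
    return state
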