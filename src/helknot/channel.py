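"""Explicit bead-built helical tubes and their analytic geometry.

A channel is a tube of constant circular cross-section (radius ``R_ch``)
whose centre line is the helix ``(R_H cos t, handedness * R_H sin t, k t)``;
the rise per turn is ``2 pi k``.  The wall is realized by stacking circles
of beads perpendicular to the centre line (Frenet frame), dense enough that
no two adjacent wall beads are more than one bead diameter apart, so a
1-sigma chain bead cannot slip through.  Wall beads are static.

``R_H = 0`` degenerates to a straight cylinder (the Frenet normal is then
undefined; any fixed perpendicular frame gives the same rotationally
symmetric tube).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize_scalar


class ChannelError(ValueError):
    pass


@dataclass(frozen=True)
class HelicalChannelSpec:
    """Parameters of a helical tube (all lengths in sigma)."""

    r_ch: float = 3.0        # tube (cross-section) radius
    r_h: float = 1.5         # helix radius
    pitch_k: float = 1.5     # rise per turn / 2 pi
    handedness: int = 1      # +1 right (omega+), -1 left (omega-)
    n_turns: float = 12.0
    bead_spacing: float = 1.0
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.r_ch <= 0:
            raise ChannelError("r_ch must be positive")
        if self.r_h < 0:
            raise ChannelError("r_h must be non-negative")
        if self.pitch_k <= 0:
            raise ChannelError("pitch_k must be positive (k = 0 undefined)")
        if self.handedness not in (-1, 1):
            raise ChannelError("handedness must be +1 or -1")
        if self.bead_spacing > 1.0 or self.bead_spacing <= 0:
            raise ChannelError("bead_spacing must be in (0, 1] sigma")
        if self.pitch_k < self.r_ch / 2:
            raise ChannelError(
                f"pitch_k = {self.pitch_k} < r_ch/2 = {self.r_ch / 2}: "
                "helix loops would extend into each other")
        if self.periodic and abs(self.n_turns - round(self.n_turns)) > 1e-9:
            raise ChannelError("periodic channels need an integer n_turns")

    @property
    def axial_period(self) -> float:
        """Axial length of one helical turn, 2 pi k."""
        return 2 * np.pi * self.pitch_k

    @property
    def axial_length(self) -> float:
        return self.axial_period * self.n_turns

    def centerline(self, t: np.ndarray) -> np.ndarray:
        """Helix centre curve at parameter t (t = angle; z = k t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.column_stack([
            self.r_h * np.cos(t),
            self.handedness * self.r_h * np.sin(t),
            self.pitch_k * t,
        ])

    def frame(self, t: np.ndarray):
        """Frenet tangent/normal/binormal along the centre line."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        h = self.handedness
        sp = np.sqrt(self.r_h**2 + self.pitch_k**2)
        tang = np.column_stack([-self.r_h * np.sin(t),
                                h * self.r_h * np.cos(t),
                                np.full_like(t, self.pitch_k)]) / sp
        # inward normal; independent of r_h, so it remains well-defined (and
        # continuous under molding) in the straight-cylinder limit r_h = 0
        normal = np.column_stack([-np.cos(t), -h * np.sin(t),
                                  np.zeros_like(t)])
        binormal = np.cross(tang, normal)
        return tang, normal, binormal

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HelicalChannelSpec":
        return cls(**d)


@dataclass
class ChannelGeometry:
    """Static wall-bead realization of a :class:`HelicalChannelSpec`."""

    wall: np.ndarray                  # (m, 3) wall-bead coordinates
    spec: HelicalChannelSpec
    n_circles: int
    beads_per_circle: int

    @property
    def axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def axial_period(self) -> float:
        return self.spec.axial_length


def build_helical_tube(spec: HelicalChannelSpec,
                       n_circles: int | None = None) -> ChannelGeometry:
    """Stack bead circles perpendicular to the helix centre line.

    Circle bead count is ceil(2 pi R_ch / spacing); circle stations are
    spaced so the fastest-moving rim point advances by at most ``spacing``
    between stations (bounded by s'(t) + R_ch per unit t for a circular
    helix).  For periodic channels the final circle is the first one's
    axial image and is omitted.
    """
    t_max = 2 * np.pi * spec.n_turns
    sp = np.sqrt(spec.r_h**2 + spec.pitch_k**2)
    if n_circles is None:
        rate = sp + spec.r_ch  # max rim speed per unit t
        n_circles = int(np.ceil(t_max * rate / spec.bead_spacing)) + 1
    # self-intersection guard: consecutive turns must clear 2 R_ch
    if spec.n_turns > 1 and spec.axial_period < 2 * spec.r_ch - 1e-9:
        raise ChannelError("tube self-intersects: axial period < tube diameter")
    m = int(np.ceil(2 * np.pi * spec.r_ch / spec.bead_spacing))
    if spec.periodic:
        ts = np.linspace(0.0, t_max, n_circles, endpoint=False)
    else:
        ts = np.linspace(0.0, t_max, n_circles)
    centers = spec.centerline(ts)
    _, normal, binormal = spec.frame(ts)
    phi = 2 * np.pi * np.arange(m) / m
    cosphi = np.cos(phi)[None, :, None]
    sinphi = np.sin(phi)[None, :, None]
    pts = (centers[:, None, :]
           + spec.r_ch * (normal[:, None, :] * cosphi
                          + binormal[:, None, :] * sinphi))
    return ChannelGeometry(pts.reshape(-1, 3), spec, len(ts), m)


def helix_geometry(spec: HelicalChannelSpec):
    """(alpha, curvature, torsion, tortuosity) of the helix centre line.

    alpha = +-R_H/k is the subtended angle; curvature kappa =
    alpha^2/[R_H (1+alpha^2)] = R_H/(R_H^2+k^2); torsion =
    alpha/[R_H (1+alpha^2)]; tortuosity = sqrt((2 pi k)^2 + (2 pi R_H)^2)
    / (2 pi k) >= 1.
    """
    if spec.pitch_k <= 0:
        raise ChannelError("pitch k = 0: geometry undefined")
    k = spec.pitch_k
    rh = spec.r_h
    alpha = spec.handedness * rh / k
    if rh == 0:
        curvature = 0.0
        torsion = 0.0
    else:
        curvature = alpha**2 / (rh * (1 + alpha**2))
        torsion = alpha / (rh * (1 + alpha**2))
    tortuosity = np.hypot(2 * np.pi * k, 2 * np.pi * rh) / (2 * np.pi * k)
    return alpha, curvature, torsion, float(tortuosity)


def wall_distance(point: np.ndarray, spec: HelicalChannelSpec) -> float:
    """Signed distance from ``point`` to the tube surface (negative inside).

    Distance to the helix centre curve (minimized numerically over the
    curve parameter) minus R_ch.  For periodic channels the axial
    coordinate is folded into one period first.
    """
    p = np.asarray(point, dtype=float)
    if spec.periodic:
        L = spec.axial_length
        p = p.copy()
        p[2] = p[2] % L
    if spec.r_h == 0:
        return float(np.hypot(p[0], p[1]) - spec.r_ch)

    def dist2(t):
        c = spec.centerline(np.array([t]))[0]
        return float(((p - c) ** 2).sum())

    t_center = p[2] / spec.pitch_k
    # coarse scan within +-1.5 turns of the point's axial station
    lo = t_center - 3 * np.pi
    hi = t_center + 3 * np.pi
    if not spec.periodic:
        lo = max(lo, 0.0)
        hi = min(hi, 2 * np.pi * spec.n_turns)
        if hi <= lo:
            lo, hi = 0.0, max(2 * np.pi * spec.n_turns, 1e-6)
    grid = np.linspace(lo, hi, 200)
    d2 = [dist2(t) for t in grid]
    i0 = int(np.argmin(d2))
    a = grid[max(i0 - 1, 0)]
    b = grid[min(i0 + 1, len(grid) - 1)]
    if a == b:
        tbest = grid[i0]
    else:
        res = minimize_scalar(dist2, bounds=(a, b), method="bounded")
        tbest = res.x if res.fun <= d2[i0] else grid[i0]
    return float(np.sqrt(dist2(tbest)) - spec.r_ch)


def mold_to_helix(current: ChannelGeometry, target: HelicalChannelSpec,
                  n_stages: int, max_step: float = 0.5):
    """Sequence of geometries deforming ``current`` into ``target``.

    The helix radius is ramped linearly over ``n_stages`` stages on a fixed
    circle/bead lattice so wall beads move smoothly; the confined chain is
    expected to relax between stages.  Raises if any stage moves a bead by
    ``max_step`` sigma or more.
    """
    if n_stages < 1:
        raise ChannelError("n_stages must be >= 1")
    cspec = current.spec
    if abs(cspec.r_ch - target.r_ch) > 1e-9:
        raise ChannelError("molding cannot change the tube radius")
    if abs(cspec.n_turns - target.n_turns) > 1e-9 or \
            abs(cspec.pitch_k - target.pitch_k) > 1e-9:
        raise ChannelError("molding requires matching tube length/pitch")
    # fixed lattice: use the densest (target) circle count
    ref = build_helical_tube(target)
    n_circ = ref.n_circles
    geoms = []
    prev = build_helical_tube(
        HelicalChannelSpec(**{**asdict(cspec)}), n_circles=n_circ)
    for s in range(1, n_stages + 1):
        frac = s / n_stages
        r_h_s = cspec.r_h + frac * (target.r_h - cspec.r_h)
        spec_s = HelicalChannelSpec(
            r_ch=target.r_ch, r_h=r_h_s, pitch_k=target.pitch_k,
            handedness=target.handedness, n_turns=target.n_turns,
            bead_spacing=target.bead_spacing, periodic=target.periodic)
        g = build_helical_tube(spec_s, n_circles=n_circ)
        step = float(np.max(np.linalg.norm(g.wall - prev.wall, axis=1)))
        if step >= max_step:
            raise ChannelError(
                f"stage {s} moves a wall bead by {step:.3f} sigma "
                f">= {max_step}; raise n_stages")
        geoms.append(g)
        prev = g
    return geoms
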