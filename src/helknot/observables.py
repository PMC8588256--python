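"""Geometric descriptors of knot cores and confined chains.

Gyration-tensor shape descriptors (R_g, asphericity A, prolateness P),
knot-core metrics (core R_g and contour length L_k in nm), channel
cross-section marker tracking, and the wall-adjusted global radius of
curvature (GRC) profile rho_G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import UnitSystem, DEFAULT_UNITS
from .topology import KnotRecord
from .channel import HelicalChannelSpec, wall_distance


@dataclass
class GyrationDescriptors:
    """Shape of a point cloud from its gyration tensor.

    A = 0 for a sphere, 1 for a rod; P < 0 oblate (disk), P > 0 prolate
    (cigar).  R_g and eigenvalues carry whatever length unit the input had.
    """

    r_g: float
    eigenvalues: tuple[float, float, float]   # descending
    asphericity: float
    prolateness: float


def gyration_descriptors(coords: np.ndarray) -> GyrationDescriptors:
    """Eigen-decompose the gyration tensor of ``coords``.

    A = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2];
    P = prod(2 li - lj - lk) / [2 (l1^2+l2^2+l3^2 - l1 l2 - l2 l3 - l3 l1)^{3/2}].
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    centred = pts - pts.mean(axis=0)
    gyr = centred.T @ centred / len(pts)
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    l1, l2, l3 = lam
    tr = lam.sum()
    if tr <= 0:
        raise ValueError("all points coincident: A and P undefined")
    asph = ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2) / (2 * tr * tr)
    denom = (l1 * l1 + l2 * l2 + l3 * l3 - l1 * l2 - l2 * l3 - l3 * l1)
    if denom < 1e-30:
        prol = 0.0
    else:
        prol = ((2 * l1 - l2 - l3) * (2 * l2 - l3 - l1) * (2 * l3 - l1 - l2)
                / (2 * denom ** 1.5))
    return GyrationDescriptors(float(np.sqrt(tr)), (l1, l2, l3),
                               float(asph), float(prol))


def knot_metrics(chain_coords: np.ndarray, knot: KnotRecord,
                 units: UnitSystem = DEFAULT_UNITS):
    """(core R_g in nm, core contour length L_k in nm) of a located core."""
    i0, i1 = knot.i_start - 1, knot.i_end - 1   # to 0-based
    if i1 - i0 + 1 < 4:
        raise ValueError("knot core shorter than 4 beads: flagged frame")
    core = np.asarray(chain_coords[i0:i1 + 1], dtype=float)
    rg_sigma = gyration_descriptors(core).r_g
    lk_sigma = float(np.linalg.norm(np.diff(core, axis=0), axis=1).sum())
    return units.convert(rg_sigma, "length"), units.convert(lk_sigma, "length")


def track_markers(chain_coords: np.ndarray, knot: KnotRecord,
                  spec: HelicalChannelSpec) -> dict:
    """Channel cross-section positions of the knot's marker beads.

    Markers: i_start, i_end, i_middle = round((i_start+i_end)/2), and the
    core centre of mass.  Each is reported as its radial distance from the
    channel's main (z) axis together with the raw coordinates; the marker
    set is invariant under relabeling the chain direction.
    """
    pts = np.asarray(chain_coords, dtype=float)
    i0, i1 = knot.i_start - 1, knot.i_end - 1
    im = knot.i_middle - 1
    com = pts[i0:i1 + 1].mean(axis=0)
    out = {}
    for name, p in (("i_start", pts[i0]), ("i_end", pts[i1]),
                    ("i_middle", pts[im]), ("core_com", com)):
        out[name] = {
            "xyz": p.copy(),
            "radial": float(np.hypot(p[0], p[1])),
        }
    return out


def grc_profile(chain_coords: np.ndarray,
                spec: HelicalChannelSpec | None = None,
                subchain: tuple[int, int] | None = None,
                min_separation: int = 2) -> np.ndarray:
    """Global radius of curvature rho_G per bead of the analyzed subchain.

    rho_G(i) is the smallest circumradius over triples (i, j, k) with j, k
    at least ``min_separation`` bonds from i (adjacent beads would give
    trivially small circles).  With a channel present the value is capped
    at the bead's distance to the wall surface, so the profile measures the
    locally available free space.  Collinear triples have infinite
    circumradius and are skipped.
    """
    pts = np.asarray(chain_coords, dtype=float)
    if subchain is not None:
        lo, hi = subchain[0] - 1, subchain[1] - 1
    else:
        lo, hi = 0, len(pts) - 1
    n = len(pts)
    out = np.full(hi - lo + 1, np.inf)
    idx_all = np.arange(n)
    for idx, i in enumerate(range(lo, hi + 1)):
        sel = idx_all[np.abs(idx_all - i) >= min_separation]
        if len(sel) < 2:
            continue
        q = pts[sel]                       # (m, 3) candidate points
        a = pts[i]
        # circumradius over all pairs (j, k) in one broadcast
        d_aj = np.linalg.norm(q - a, axis=1)          # (m,)
        diff = q[None, :, :] - q[:, None, :]          # (m, m, 3)
        d_jk = np.linalg.norm(diff, axis=2)           # (m, m)
        cross = np.linalg.norm(
            np.cross((q - a)[:, None, :], (q - a)[None, :, :]), axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            rad = d_aj[:, None] * d_aj[None, :] * d_jk / (2.0 * cross)
        rad[cross < 1e-12] = np.inf
        np.fill_diagonal(rad, np.inf)
        out[idx] = min(out[idx], float(np.nanmin(rad)))
    if spec is not None:
        for idx, i in enumerate(range(lo, hi + 1)):
            cap = abs(wall_distance(pts[i], spec))
            out[idx] = min(out[idx], cap)
    return out


def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ab = np.linalg.norm(b - a)
    bc = np.linalg.norm(c - b)
    ca = np.linalg.norm(a - c)
    cross = np.linalg.norm(np.cross(b - a, c - a))
    if cross < 1e-12:
        return np.inf
    return float(ab * bc * ca / (2.0 * cross))
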