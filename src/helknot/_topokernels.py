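"""Numba kernels for knot-topology analysis.

Hot-path geometry/algebra used by :mod:`helknot.topology`:

* KMT (Koniaris-Muthukumar-Taylor) chain reduction: iteratively delete a
  vertex whenever the triangle it spans with its neighbours is crossed by no
  other chain segment (an isotopy of the curve).
* Gauss double-sum writhe over non-adjacent segment pairs (the exact
  polygonal solid-angle form of Klenin & Langowski).
* Crossing extraction from a z-projection of a closed polygon.
* Alexander-matrix determinant magnitudes |Delta(-1)|, |Delta(-2)| computed
  exactly by modular evaluation/interpolation over the prime 2^31 - 1.  The
  Wirtinger determinant equals +-t^a * Delta(t); interpolating the whole
  polynomial and stripping the monomial factor removes the +-t^a ambiguity
  that makes naive evaluation at t = -2 ill-defined.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_P = 2147483647  # Mersenne prime 2^31 - 1; all modular arithmetic fits int64
_EPS = 1e-9


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cross3(a, b):
    return np.array((a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]))


@njit(cache=True)
def _seg_triangle_intersect(p0, p1, a, b, c):
    """Does the open segment p0-p1 cross triangle (a, b, c)?

    Conservative on borderline cases (returns True), except for the
    coplanar case which is resolved by a 2-D overlap test so that planar
    chains still reduce.
    """
    e1 = b - a
    e2 = c - a
    d = p1 - p0
    h = _cross3(d, e2)
    det = e1[0] * h[0] + e1[1] * h[1] + e1[2] * h[2]
    nrm = _cross3(e1, e2)
    scale = max(np.sqrt(nrm[0] ** 2 + nrm[1] ** 2 + nrm[2] ** 2), _EPS)
    if abs(det) > 1e-12 * max(scale, 1.0):
        inv = 1.0 / det
        s = p0 - a
        u = (s[0] * h[0] + s[1] * h[1] + s[2] * h[2]) * inv
        if u < -1e-10 or u > 1.0 + 1e-10:
            return False
        q = _cross3(s, e1)
        v = (d[0] * q[0] + d[1] * q[1] + d[2] * q[2]) * inv
        if v < -1e-10 or u + v > 1.0 + 1e-10:
            return False
        t = (e2[0] * q[0] + e2[1] * q[1] + e2[2] * q[2]) * inv
        return -1e-10 <= t <= 1.0 + 1e-10
    # segment parallel to the triangle plane
    dist0 = ((p0[0] - a[0]) * nrm[0] + (p0[1] - a[1]) * nrm[1]
             + (p0[2] - a[2]) * nrm[2]) / scale
    if abs(dist0) > 1e-8 * max(1.0, scale):
        return False
    # coplanar: 2-D test in the dominant plane of the triangle normal
    ax = abs(nrm[0])
    ay = abs(nrm[1])
    az = abs(nrm[2])
    if az >= ax and az >= ay:
        i0, i1 = 0, 1
    elif ay >= ax:
        i0, i1 = 0, 2
    else:
        i0, i1 = 1, 2
    return _seg_tri_2d(p0[i0], p0[i1], p1[i0], p1[i1],
                       a[i0], a[i1], b[i0], b[i1], c[i0], c[i1])


@njit(cache=True)
def _seg_seg_2d(ax, ay, bx, by, cx, cy, dx, dy):
    ux = bx - ax
    uy = by - ay
    vx = dx - cx
    vy = dy - cy
    den = ux * vy - uy * vx
    wx = cx - ax
    wy = cy - ay
    if abs(den) < 1e-14:
        # parallel: overlap iff collinear and ranges intersect
        if abs(wx * uy - wy * ux) > 1e-10:
            return False
        # project onto u
        uu = ux * ux + uy * uy
        if uu < 1e-20:
            return False
        t0 = (wx * ux + wy * uy) / uu
        t1 = ((dx - ax) * ux + (dy - ay) * uy) / uu
        lo = min(t0, t1)
        hi = max(t0, t1)
        return hi >= -1e-10 and lo <= 1.0 + 1e-10
    s = (wx * vy - wy * vx) / den
    t = (wx * uy - wy * ux) / den
    return -1e-10 <= s <= 1 + 1e-10 and -1e-10 <= t <= 1 + 1e-10


@njit(cache=True)
def _point_in_tri_2d(px, py, ax, ay, bx, by, cx, cy):
    d1 = (px - bx) * (ay - by) - (ax - bx) * (py - by)
    d2 = (px - cx) * (by - cy) - (bx - cx) * (py - cy)
    d3 = (px - ax) * (cy - ay) - (cx - ax) * (py - ay)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


@njit(cache=True)
def _seg_tri_2d(px, py, qx, qy, ax, ay, bx, by, cx, cy):
    if _point_in_tri_2d(px, py, ax, ay, bx, by, cx, cy):
        return True
    if _point_in_tri_2d(qx, qy, ax, ay, bx, by, cx, cy):
        return True
    if _seg_seg_2d(px, py, qx, qy, ax, ay, bx, by):
        return True
    if _seg_seg_2d(px, py, qx, qy, bx, by, cx, cy):
        return True
    return _seg_seg_2d(px, py, qx, qy, cx, cy, ax, ay)


# ---------------------------------------------------------------------------
# KMT reduction
# ---------------------------------------------------------------------------

@njit(cache=True)
def kmt_alive_mask(coords, closed):
    """Boolean mask of vertices surviving KMT reduction.

    Open chains keep both endpoints; closed chains reduce to >= 3 vertices.
    """
    n = coords.shape[0]
    alive = np.ones(n, np.bool_)
    nxt = np.empty(n, np.int64)
    prv = np.empty(n, np.int64)
    for i in range(n):
        nxt[i] = (i + 1) % n
        prv[i] = (i - 1) % n
    count = n
    min_count = 3 if closed else 2
    changed = True
    while changed and count > min_count:
        changed = False
        for v in range(n):
            if count <= min_count:
                break
            if not alive[v]:
                continue
            if (not closed) and (v == 0 or v == n - 1):
                continue
            u = prv[v]
            w = nxt[v]
            a = coords[u]
            b = coords[v]
            c = coords[w]
            # test every alive segment not touching u, v, w
            hit = False
            s = 0 if not closed else u
            if not closed:
                while not alive[s]:
                    s += 1
            first = s
            visited = 0
            while visited < count:
                visited += 1
                if (not closed) and s == n - 1:
                    break
                e = nxt[s]
                if s != u and s != v and s != w and e != u and e != v and e != w:
                    if _seg_triangle_intersect(coords[s], coords[e], a, b, c):
                        hit = True
                        break
                s = e
                if closed and s == first:
                    break
            if not hit:
                alive[v] = False
                nxt[u] = w
                prv[w] = u
                count -= 1
                changed = True
    return alive


# ---------------------------------------------------------------------------
# writhe
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_solid_angle(p1, p2, p3, p4):
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = _cross3(r13, r14)
    n2 = _cross3(r14, r24)
    n3 = _cross3(r24, r23)
    n4 = _cross3(r23, r13)
    l1 = np.sqrt(n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2)
    l2 = np.sqrt(n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2)
    l3 = np.sqrt(n3[0] ** 2 + n3[1] ** 2 + n3[2] ** 2)
    l4 = np.sqrt(n4[0] ** 2 + n4[1] ** 2 + n4[2] ** 2)
    if l1 < 1e-12 or l2 < 1e-12 or l3 < 1e-12 or l4 < 1e-12:
        return 0.0
    a1 = (n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]) / (l1 * l2)
    a2 = (n2[0] * n3[0] + n2[1] * n3[1] + n2[2] * n3[2]) / (l2 * l3)
    a3 = (n3[0] * n4[0] + n3[1] * n4[1] + n3[2] * n4[2]) / (l3 * l4)
    a4 = (n4[0] * n1[0] + n4[1] * n1[1] + n4[2] * n1[2]) / (l4 * l1)
    a1 = min(1.0, max(-1.0, a1))
    a2 = min(1.0, max(-1.0, a2))
    a3 = min(1.0, max(-1.0, a3))
    a4 = min(1.0, max(-1.0, a4))
    omega = np.arcsin(a1) + np.arcsin(a2) + np.arcsin(a3) + np.arcsin(a4)
    r34 = p4 - p3
    r12 = p2 - p1
    cr = _cross3(r34, r12)
    sgn = cr[0] * r13[0] + cr[1] * r13[1] + cr[2] * r13[2]
    if sgn > 0:
        return omega
    elif sgn < 0:
        return -omega
    return 0.0


@njit(cache=True)
def writhe_gauss(coords, closed):
    """Discrete Gauss-integral writhe of a polygonal curve."""
    n = coords.shape[0]
    nseg = n if closed else n - 1
    wr = 0.0
    for i in range(nseg):
        i2 = (i + 1) % n
        for j in range(i + 2, nseg):
            if closed and i == 0 and j == nseg - 1:
                continue
            j2 = (j + 1) % n
            wr += _pair_solid_angle(coords[i], coords[i2], coords[j], coords[j2])
    return wr / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# crossings of a projected closed polygon
# ---------------------------------------------------------------------------

@njit(cache=True)
def find_crossings(coords):
    """Crossings of the z-projection of closed polygon ``coords``.

    Returns (ok, seg_i, par_i, seg_j, par_j, sign, over) where over=0 means
    the ``i`` strand passes over.  ok=False signals a degenerate projection
    (crossing at a vertex, parallel overlap, or ambiguous depth): the caller
    should re-rotate and retry.
    """
    n = coords.shape[0]
    cap = n * n // 2 + 8
    seg_i = np.empty(cap, np.int64)
    par_i = np.empty(cap, np.float64)
    seg_j = np.empty(cap, np.int64)
    par_j = np.empty(cap, np.float64)
    sgn = np.empty(cap, np.int64)
    over = np.empty(cap, np.int64)
    m = 0
    tol = 1e-9
    for i in range(n):
        i2 = (i + 1) % n
        ax = coords[i, 0]
        ay = coords[i, 1]
        ux = coords[i2, 0] - ax
        uy = coords[i2, 1] - ay
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            j2 = (j + 1) % n
            cx = coords[j, 0]
            cy = coords[j, 1]
            vx = coords[j2, 0] - cx
            vy = coords[j2, 1] - cy
            den = ux * vy - uy * vx
            wx = cx - ax
            wy = cy - ay
            if abs(den) < 1e-13:
                # parallel in projection: degenerate only if collinear overlap
                if abs(wx * uy - wy * ux) < tol:
                    return False, seg_i[:0], par_i[:0], seg_j[:0], par_j[:0], sgn[:0], over[:0]
                continue
            s = (wx * vy - wy * vx) / den
            t = (wx * uy - wy * ux) / den
            if s < -tol or s > 1 + tol or t < -tol or t > 1 + tol:
                continue
            if s < tol or s > 1 - tol or t < tol or t > 1 - tol:
                # crossing at/near a vertex -> degenerate projection
                return False, seg_i[:0], par_i[:0], seg_j[:0], par_j[:0], sgn[:0], over[:0]
            z1 = coords[i, 2] + s * (coords[i2, 2] - coords[i, 2])
            z2 = coords[j, 2] + t * (coords[j2, 2] - coords[j, 2])
            if abs(z1 - z2) < tol:
                return False, seg_i[:0], par_i[:0], seg_j[:0], par_j[:0], sgn[:0], over[:0]
            if m >= cap:
                return False, seg_i[:0], par_i[:0], seg_j[:0], par_j[:0], sgn[:0], over[:0]
            seg_i[m] = i
            par_i[m] = s
            seg_j[m] = j
            par_j[m] = t
            # crossing sign: +1 if (over x under) z-component > 0
            if z1 > z2:
                cz = ux * vy - uy * vx
                over[m] = 0
            else:
                cz = vx * uy - vy * ux
                over[m] = 1
            sgn[m] = 1 if cz > 0 else -1
            m += 1
    return True, seg_i[:m], par_i[:m], seg_j[:m], par_j[:m], sgn[:m], over[:m]


# ---------------------------------------------------------------------------
# modular Alexander determinant
# ---------------------------------------------------------------------------

@njit(cache=True)
def _det_mod(mat, p):
    """Determinant of an int64 matrix mod p (Gaussian elimination)."""
    a = mat.copy()
    n = a.shape[0]
    if n == 0:
        return 1
    det = 1
    sign = 1
    for col in range(n):
        piv = -1
        for r in range(col, n):
            if a[r, col] % p != 0:
                piv = r
                break
        if piv == -1:
            return 0
        if piv != col:
            for c in range(n):
                tmp = a[col, c]
                a[col, c] = a[piv, c]
                a[piv, c] = tmp
            sign = -sign
        pval = a[col, col] % p
        det = (det * pval) % p
        # inverse of pval mod p by Fermat
        inv = 1
        base = pval
        e = p - 2
        while e > 0:
            if e & 1:
                inv = (inv * base) % p
            base = (base * base) % p
            e >>= 1
        for r in range(col + 1, n):
            factor = (a[r, col] % p * inv) % p
            if factor == 0:
                continue
            for c in range(col, n):
                a[r, c] = (a[r, c] - factor * a[col, c]) % p
    if sign < 0:
        det = (p - det) % p
    return det


@njit(cache=True)
def alexander_pair_from_crossings(seg_i, par_i, seg_j, par_j, sgn, over):
    """(|Delta(-1)|, |Delta(-2)|) from a crossing list.

    Builds the Wirtinger Alexander matrix (rows = crossings, columns = arcs),
    deletes one column, and recovers the determinant polynomial exactly by
    modular interpolation; the +-t^a normalisation factor is stripped before
    evaluating at t = -1 and t = -2.  Returns (-1, -1) if the diagram is
    degenerate (identically-zero determinant).
    """
    c = seg_i.shape[0]
    if c == 0:
        return 1, 1
    # order the 2c passages along the curve
    pos_seg = np.empty(2 * c, np.float64)
    pass_cross = np.empty(2 * c, np.int64)
    pass_under = np.empty(2 * c, np.bool_)
    for k in range(c):
        pos_seg[2 * k] = seg_i[k] + par_i[k]
        pass_cross[2 * k] = k
        pass_under[2 * k] = over[k] == 1
        pos_seg[2 * k + 1] = seg_j[k] + par_j[k]
        pass_cross[2 * k + 1] = k
        pass_under[2 * k + 1] = over[k] == 0
    order = np.argsort(pos_seg)
    # arc index of each passage: number of under-passages strictly before it,
    # with the wrap-around arc identified (mod #under = c)
    arc_at = np.empty(2 * c, np.int64)
    n_under = 0
    for idx in range(2 * c):
        pidx = order[idx]
        if pass_under[pidx]:
            n_under += 1
            # an under passage terminates the current arc; record the arc it
            # arrives on as the current count-1's... handled below
        arc_at[pidx] = n_under
    # passages after the last under wrap to arc 0; total arcs = c
    over_arc = np.empty(c, np.int64)
    in_arc = np.empty(c, np.int64)
    out_arc = np.empty(c, np.int64)
    for idx in range(2 * c):
        pidx = order[idx]
        k = pass_cross[pidx]
        if pass_under[pidx]:
            # this passage sits at the boundary: incoming arc is the arc
            # before the increment, outgoing is after
            in_arc[k] = (arc_at[pidx] - 1) % c
            out_arc[k] = arc_at[pidx] % c
        else:
            over_arc[k] = arc_at[pidx] % c
    # polynomial matrix M0 + t*M1
    m0 = np.zeros((c, c), np.int64)
    m1 = np.zeros((c, c), np.int64)
    for k in range(c):
        io = over_arc[k]
        ju = in_arc[k]
        lu = out_arc[k]
        # row: (1 - t) a_io + t a_ju - a_lu = 0   (positive crossing)
        #      (t - 1) a_io + a_ju - t a_lu = 0   (negative crossing)
        # both sum to zero, as the abelianized Wirtinger relations must
        if sgn[k] > 0:
            m0[k, io] += 1
            m1[k, io] -= 1
            m1[k, ju] += 1
            m0[k, lu] -= 1
        else:
            m0[k, io] -= 1
            m1[k, io] += 1
            m0[k, ju] += 1
            m1[k, lu] -= 1
    # delete last column -> (c) x (c-1); use rows 0..c-2? delete last row too:
    # any (c-1)x(c-1) minor works (rows are dependent)
    p = _P
    d = c - 1
    vals = np.empty(c, np.int64)
    sub = np.empty((d, d), np.int64)
    for tval in range(c):
        for r in range(d):
            for cc in range(d):
                sub[r, cc] = (m0[r, cc] + tval * m1[r, cc]) % p
        vals[tval] = _det_mod(sub, p)
    # Lagrange interpolation at nodes 0..c-1 -> coefficients mod p
    coeffs = np.zeros(c, np.int64)
    basis = np.zeros(c + 1, np.int64)
    for node in range(c):
        # build polynomial prod_{m != node} (x - m) / (node - m)
        poly = np.zeros(c, np.int64)
        poly[0] = 1
        deg = 0
        denom = 1
        for mnode in range(c):
            if mnode == node:
                continue
            denom = (denom * ((node - mnode) % p)) % p
            # multiply poly by (x - mnode)
            for q in range(deg, -1, -1):
                basis[q + 1] = poly[q]
            basis[0] = 0
            for q in range(deg + 1):
                basis[q] = (basis[q] - mnode * poly[q]) % p
            deg += 1
            for q in range(deg + 1):
                poly[q] = basis[q] % p
        # inverse of denom
        inv = 1
        base = denom % p
        e = p - 2
        while e > 0:
            if e & 1:
                inv = (inv * base) % p
            base = (base * base) % p
            e >>= 1
        w = (vals[node] * inv) % p
        for q in range(c):
            coeffs[q] = (coeffs[q] + w * poly[q]) % p
    # strip t^a factor
    lo = -1
    for q in range(c):
        if coeffs[q] % p != 0:
            lo = q
            break
    if lo < 0:
        return -1, -1
    d1 = 0
    d2 = 0
    tpow1 = 1
    tpow2 = 1
    for q in range(lo, c):
        d1 = (d1 + coeffs[q] * tpow1) % p
        d2 = (d2 + coeffs[q] * tpow2) % p
        tpow1 = (tpow1 * (p - 1)) % p
        tpow2 = (tpow2 * (p - 2)) % p
    if d1 > p // 2:
        d1 = p - d1
    if d2 > p // 2:
        d2 = p - d2
    return d1, d2
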