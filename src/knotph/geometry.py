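"""Geometric compactness measures for polygonal knots.

Covers the radius of gyration, the exact minimal enclosing sphere (Welzl's
algorithm), convex-hull volume, discrete total curvature (turning angles),
discrete torsion (consecutive osculating-plane dihedrals), and the average
crossing number (ACN), estimated both by Monte-Carlo averaging of projected
crossing counts over the sphere of directions and by the Gauss double
integral.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from knotph.polygon import PolygonKnot


@dataclass(frozen=True)
class GeometricSummary:
    """Per-polygon geometry record; attribute names match the CSV columns."""

    Rg: float
    RS: float
    V_sphere: float
    V_hull: float
    curv_total: float
    tors_signed: float
    tors_abs: float
    acn: float
    acn_stderr: float

    COLUMNS = ("Rg", "RS", "V_sphere", "V_hull", "curv_total",
               "tors_signed", "tors_abs", "acn", "acn_stderr")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.COLUMNS}


def radius_of_gyration(P: PolygonKnot) -> float:
    """Root-mean-square distance of the vertices from their centroid."""
    v = P.vertices
    c = v.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((v - c) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# minimal enclosing sphere (Welzl)
# ---------------------------------------------------------------------------

def _circumsphere(boundary: np.ndarray):
    """Sphere through all boundary points (<= 4), minimal for <= 2; None if degenerate."""
    k = len(boundary)
    if k == 0:
        return None
    if k == 1:
        return boundary[0], 0.0
    p0 = boundary[0]
    B = boundary[1:] - p0
    G = B @ B.T
    h = 0.5 * np.diag(G)
    try:
        lam = np.linalg.solve(G, h)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(lam)):
        return None
    center = p0 + lam @ B
    r = float(np.linalg.norm(center - p0))
    return center, r


def _welzl(pts: np.ndarray, order: list, end: int, boundary: list):
    if end == 0 or len(boundary) == 4:
        return _circumsphere(np.array(boundary).reshape(-1, 3))
    idx = order[end - 1]
    ball = _welzl(pts, order, end - 1, boundary)
    if ball is not None:
        center, r = ball
        if np.linalg.norm(pts[idx] - center) <= r * (1 + 1e-12) + 1e-12:
            return ball
    return _welzl(pts, order, end - 1, boundary + [pts[idx]])


def min_enclosing_sphere(points) -> tuple[np.ndarray, float]:
    """Exact minimal enclosing ball of a 3D point set.

    Welzl's randomized recursion over (when possible) the convex-hull
    vertices only.  All points lie inside the returned sphere within 1e-9.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    work = pts
    if pts.shape[0] > 64:
        try:
            work = pts[np.unique(ConvexHull(pts).vertices)]
        except QhullError:
            work = pts
    rng = np.random.default_rng(1234)  # fixed: result is order-independent
    order = list(rng.permutation(work.shape[0]))
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 2 * len(order) + 100))
    try:
        ball = _welzl(work, order, len(order), [])
    finally:
        sys.setrecursionlimit(old_limit)
    if ball is None:  # all points coincident (or numerically so)
        center = pts.mean(axis=0)
        return center, float(np.max(np.linalg.norm(pts - center, axis=1)))
    center, r = ball
    r = max(r, float(np.max(np.linalg.norm(pts - center, axis=1))))
    return center, r


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * np.pi * float(radius) ** 3


def hull_volume(points) -> float:
    """Convex hull volume; degenerate (coplanar) input yields 0 with a warning."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate point set: convex hull volume set to 0",
                      stacklevel=2)
        return 0.0


def total_curvature(P: PolygonKnot) -> float:
    """Sum of turning angles between consecutive edges, in radians (>= 2 pi)."""
    e = P.edges()
    u = e / np.linalg.norm(e, axis=1, keepdims=True)
    dots = np.clip(np.sum(u * np.roll(u, -1, axis=0), axis=1), -1.0, 1.0)
    return float(np.sum(np.arccos(dots)))


def total_torsion(P: PolygonKnot) -> tuple[float, float]:
    """(signed sum, absolute sum) of dihedral angles between osculating planes.

    The plane at edge i is spanned by (e_{i-1}, e_i); the signed dihedral to
    the next plane is measured about e_i with the right-hand rule.  A vertex
    with collinear neighbours contributes 0.
    """
    e = P.edges()
    u = e / np.linalg.norm(e, axis=1, keepdims=True)
    b = np.cross(np.roll(u, 1, axis=0), u)  # binormal of (e_{i-1}, e_i)
    signed = 0.0
    absolute = 0.0
    n = len(u)
    for i in range(n):
        b1, b2 = b[i], b[(i + 1) % n]
        n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        x = float(b1 @ b2)
        y = float(np.cross(b1, b2) @ u[i])
        ang = np.arctan2(y, x)
        signed += ang
        absolute += abs(ang)
    return float(signed), float(absolute)


# ---------------------------------------------------------------------------
# average crossing number
# ---------------------------------------------------------------------------

def _pair_indices(n: int):
    idx_i, idx_j = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue
            idx_i.append(i)
            idx_j.append(j)
    return np.array(idx_i), np.array(idx_j)


def _count_crossings(xy: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray,
                     tol: float):
    """Transverse crossing count of the projected polygon; None if degenerate."""
    n = xy.shape[0]
    seg = np.roll(xy, -1, axis=0) - xy
    pi, pj = xy[idx_i], xy[idx_j]
    di, dj = seg[idx_i], seg[idx_j]
    det = di[:, 0] * dj[:, 1] - di[:, 1] * dj[:, 0]
    r = pj - pi
    near_parallel = np.abs(det) < tol
    safe_det = np.where(near_parallel, 1.0, det)
    t = (r[:, 0] * dj[:, 1] - r[:, 1] * dj[:, 0]) / safe_det
    u = (r[:, 0] * di[:, 1] - r[:, 1] * di[:, 0]) / safe_det
    inside = (~near_parallel & (t > tol) & (t < 1 - tol)
              & (u > tol) & (u < 1 - tol))
    marginal = (~near_parallel
                & (t > -tol) & (t < 1 + tol) & (u > -tol) & (u < 1 + tol)
                & ~inside)
    if np.any(marginal):
        return None
    return int(np.count_nonzero(inside))


def acn_projection_mc(P: PolygonKnot, n_dirs: int = 100,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[float, float]:
    """Monte-Carlo ACN: mean projected crossing count over random directions.

    Directions are uniform on the sphere; degenerate ones are resampled.
    Returns (mean, standard error); the projection average is already the
    normalized ACN.
    """
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    rng = np.random.default_rng(rng)
    n = P.n
    idx_i, idx_j = _pair_indices(n)
    counts = np.empty(n_dirs)
    got = 0
    attempts = 0
    while got < n_dirs:
        attempts += 1
        if attempts > 50 * n_dirs:
            raise RuntimeError("too many degenerate projection directions")
        d = rng.normal(size=3)
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            continue
        d /= nd
        a = np.zeros(3)
        a[np.argmin(np.abs(d))] = 1.0
        e1 = np.cross(d, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        xy = np.column_stack([P.vertices @ e1, P.vertices @ e2])
        c = _count_crossings(xy, idx_i, idx_j, 1e-9)
        if c is None:
            continue
        counts[got] = c
        got += 1
    mean = float(np.mean(counts))
    stderr = float(np.std(counts, ddof=1) / np.sqrt(n_dirs)) if n_dirs > 1 else 0.0
    return mean, stderr


def _clip_halfplane(poly, coeffs, keep_positive):
    """Sutherland-Hodgman clip of a convex polygon against A0 + A1 t + A2 s >= 0."""
    a0, a1, a2 = coeffs
    sign = 1.0 if keep_positive else -1.0
    out = []
    m = len(poly)
    for k in range(m):
        p, q = poly[k], poly[(k + 1) % m]
        fp = sign * (a0 + a1 * p[0] + a2 * p[1])
        fq = sign * (a0 + a1 * q[0] + a2 * q[1])
        if fp >= 0:
            out.append(p)
        if (fp > 0) != (fq > 0) and fp != fq:
            lam = fp / (fp - fq)
            if 0.0 < lam < 1.0:
                out.append((p[0] + lam * (q[0] - p[0]),
                            p[1] + lam * (q[1] - p[1])))
    return out


def _pair_integral(r0, ei, ej, cr, nodes, W2, duffy):
    """Integral of |cr . (r0 + t e_i - s e_j)| / |r0 + t e_i - s e_j|^3.

    The numerator is affine in (t, s), so its zero set is a line: where the
    sign is constant the tensor Gauss rule applies directly; otherwise the
    unit square is split along the line and each smooth piece is integrated
    by a Duffy-mapped triangle rule.
    """
    a0 = float(cr @ r0)
    a1 = float(cr @ ei)
    a2 = -float(cr @ ej)

    def smooth(ts):
        diff = (r0[None, :] + ts[:, 0, None] * ei[None, :]
                - ts[:, 1, None] * ej[None, :])
        num = a0 + a1 * ts[:, 0] + a2 * ts[:, 1]
        return num / np.sum(diff * diff, axis=1) ** 1.5

    corners = [a0, a0 + a1, a0 + a2, a0 + a1 + a2]
    if min(corners) >= 0 or max(corners) <= 0:
        ts = np.column_stack([np.repeat(nodes, len(nodes)),
                              np.tile(nodes, len(nodes))])
        return abs(float(W2 @ smooth(ts)))

    square = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    du, dv, dw = duffy
    total = 0.0
    for keep_positive in (True, False):
        poly = _clip_halfplane(square, (a0, a1, a2), keep_positive)
        if len(poly) < 3:
            continue
        A = np.array(poly[0])
        for k in range(1, len(poly) - 1):
            B, C = np.array(poly[k]), np.array(poly[k + 1])
            area2 = abs((B[0] - A[0]) * (C[1] - A[1])
                        - (B[1] - A[1]) * (C[0] - A[0]))
            if area2 < 1e-15:
                continue
            ts = (A[None, :] + du[:, None] * (B - A)[None, :]
                  + (du * dv)[:, None] * (C - B)[None, :])
            total += abs(float((dw * area2) @ smooth(ts)))
    return total


def _segment_distance(p, dp, q, dq):
    """Minimal distance between segments p + t dp and q + s dq, t, s in [0,1]."""
    r = p - q
    a, b, c = dp @ dp, dp @ dq, dq @ dq
    d, e = dp @ r, dq @ r
    denom = a * c - b * b
    if denom > 1e-14:
        t = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        t = 0.0
    s = np.clip((b * t + e) / c, 0.0, 1.0) if c > 1e-14 else 0.0
    t = np.clip((b * s - d) / a, 0.0, 1.0) if a > 1e-14 else t
    return float(np.linalg.norm(r + t * dp - s * dq))


def acn_gauss_integral(P: PolygonKnot, quad_order: int = 8) -> float:
    """ACN via the Gauss double integral with Gauss-Legendre quadrature.

    acn = (1/4pi) * sum over ordered non-adjacent segment pairs of
    |(e_i x e_j) . (x(t) - y(s))| / |x - y|^3 integrated over both segments.
    Adjacent pairs vanish exactly (the triple product of coplanar vectors).
    Two refinements keep the rule at full order: each pair's parameter square
    is split along the straight zero line of the numerator (an affine
    function), and pairs of nearly touching segments are subdivided into
    sub-squares comparable to their separation before applying the rule.
    """
    if quad_order < 2:
        raise ValueError("quad_order must be >= 2")
    v = P.vertices
    e = P.edges()
    n = P.n
    nodes, weights = np.polynomial.legendre.leggauss(quad_order)
    nodes = 0.5 * (nodes + 1.0)
    weights = 0.5 * weights
    W2 = np.outer(weights, weights).ravel()
    # Duffy map nodes for triangle pieces
    du = np.repeat(nodes, len(nodes))
    dv = np.tile(nodes, len(nodes))
    dw = W2 * du
    duffy = (du, dv, dw)
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            cr = np.cross(e[i], e[j])
            if np.linalg.norm(cr) < 1e-14:
                continue
            dmin = _segment_distance(v[i], e[i], v[j], e[j])
            k = 1 if dmin >= 0.5 else min(12, int(np.ceil(1.0 / max(dmin, 0.085))))
            if k == 1:
                total += 2.0 * _pair_integral(v[i] - v[j], e[i], e[j], cr,
                                              nodes, W2, duffy)
            else:
                ei, ej = e[i] / k, e[j] / k
                crk = cr / (k * k)
                for mi in range(k):
                    pi = v[i] + (mi / k) * e[i]
                    for mj in range(k):
                        r0 = pi - (v[j] + (mj / k) * e[j])
                        total += 2.0 * _pair_integral(r0, ei, ej, crk,
                                                      nodes, W2, duffy)
    return total / (4.0 * np.pi)


def geometric_summary(P: PolygonKnot, n_dirs: int = 100,
                      rng: np.random.Generator | int | None = None
                      ) -> GeometricSummary:
    """Compute every geometric feature of a polygon in one pass."""
    center, RS = min_enclosing_sphere(P.vertices)
    tors_signed, tors_abs = total_torsion(P)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vh = hull_volume(P.vertices)
    acn, acn_stderr = acn_projection_mc(P, n_dirs=n_dirs, rng=rng)
    return GeometricSummary(
        Rg=radius_of_gyration(P),
        RS=RS,
        V_sphere=sphere_volume(RS),
        V_hull=vh,
        curv_total=total_curvature(P),
        tors_signed=tors_signed,
        tors_abs=tors_abs,
        acn=acn,
        acn_stderr=acn_stderr,
    )
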