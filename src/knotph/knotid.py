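"""Knot type identification for polygonal curves.

A polygon is projected along a generic direction to a knot diagram (signed
Gauss code), the diagram is reduced by Reidemeister I/II simplifications, and
its Alexander polynomial is computed from the crossing/arc presentation.  The
normalized polynomial is looked up in a reference table covering the unknot
and all prime knot types through six crossings; anything else is labelled
``"unknown"``.  Classification is repeated over several random projection
directions with majority voting, since a generic projection of a fixed curve
always yields the same invariant.

The Alexander polynomial distinguishes all prime knots through 6 crossings.
Two caveats are inherited from the invariant itself: knots with trivial
Alexander polynomial are labelled ``0_1`` (the first nontrivial examples have
11 crossings), and >=7-crossing types whose polynomial coincides with a table
entry would be mislabelled (none exist through 8 crossings for this table).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

DEGENERACY_TOL = 1e-9
#: retry budget for degenerate projections inside classify()
MAX_DIRECTIONS = 20

# primes just below 2^31 (products with 31-bit residues stay within int64)
_PRIMES = (2147483647, 2147483629, 2147483587, 2147483579, 2147483563,
           2147483549, 2147483543, 2147483497, 2147483489, 2147483477)


class DegenerateProjection(RuntimeError):
    """The projection direction is non-generic for this polygon."""


class ClassificationFailure(RuntimeError):
    """All attempted projection directions were degenerate."""


@dataclass(frozen=True)
class LaurentPoly:
    """Integer Laurent polynomial, normalized so deg starts at 0 and p(1) = +1.

    Alexander polynomials are defined up to units +-t^k; the normalized
    coefficient tuple is therefore a complete representation.
    """

    coeffs: tuple

    def __post_init__(self):
        c = tuple(int(x) for x in self.coeffs)
        if not c or all(x == 0 for x in c):
            raise ValueError("zero polynomial cannot be normalized")
        lo = next(i for i, x in enumerate(c) if x != 0)
        hi = next(i for i in range(len(c) - 1, -1, -1) if c[i] != 0)
        c = c[lo:hi + 1]
        s = sum(c)
        if abs(s) != 1:
            raise ValueError(f"not a knot Alexander polynomial: p(1) = {s}")
        if s < 0:
            c = tuple(-x for x in c)
        object.__setattr__(self, "coeffs", tuple(c))

    def __call__(self, t: float) -> float:
        return float(sum(a * t ** i for i, a in enumerate(self.coeffs)))

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def is_palindromic(self) -> bool:
        return self.coeffs == self.coeffs[::-1]


#: normalized Alexander coefficient sequences of the supported knot types
ALEXANDER_TABLE = {
    (1,): "0_1",
    (1, -1, 1): "3_1",
    (-1, 3, -1): "4_1",
    (1, -1, 1, -1, 1): "5_1",
    (2, -3, 2): "5_2",
    (-2, 5, -2): "6_1",
    (-1, 3, -3, 3, -1): "6_2",
    (1, -3, 5, -3, 1): "6_3",
}

SUPPORTED_TYPES = tuple(ALEXANDER_TABLE.values())


@dataclass(frozen=True)
class KnotDiagram:
    """Signed Gauss code: crossing ids and over/under flags along the curve.

    ``code[k] = (crossing id, is_over)`` for the k-th crossing passage met
    along the curve; each id appears exactly twice, once over and once under.
    ``signs[id]`` is the crossing sign under the right-handed convention.
    """

    code: tuple
    signs: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = Counter(cid for cid, _ in self.code)
        for cid, cnt in counts.items():
            if cnt != 2:
                raise ValueError(f"crossing {cid} appears {cnt} times")
            flags = {over for c, over in self.code if c == cid}
            if flags != {True, False}:
                raise ValueError(f"crossing {cid} lacks an over or under passage")
        object.__setattr__(self, "signs", dict(self.signs))

    @property
    def n_crossings(self) -> int:
        return len(self.code) // 2


def _projection_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    a = np.zeros(3)
    a[np.argmin(np.abs(d))] = 1.0
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)  # (e1, e2, d) is a right-handed frame
    return e1, e2


def project_to_diagram(P, direction, tol: float = DEGENERACY_TOL) -> KnotDiagram:
    """Project the polygon along ``direction`` and read off the signed Gauss code.

    Crossings are transverse intersections of non-adjacent projected edges;
    the strand with larger component along ``direction`` passes over.  Any
    near-degeneracy (near-parallel overlap, crossing within ``tol`` of a
    vertex image, near-equal depths, near-coincident crossings on one edge)
    raises :class:`DegenerateProjection`; the caller retries with a fresh
    random direction.
    """
    e1, e2 = _projection_frame(direction)
    d = np.asarray(direction, dtype=float)
    V = P.vertices
    n = V.shape[0]
    xy = np.column_stack([V @ e1, V @ e2])
    depth = V @ d
    seg = np.roll(xy, -1, axis=0) - xy
    if np.min(np.linalg.norm(seg, axis=1)) < tol:
        raise DegenerateProjection("an edge projects to a point")

    passages = []  # (edge index, param along edge, crossing id, is_over)
    signs = {}
    cid = 0
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            det = seg[i, 0] * seg[j, 1] - seg[i, 1] * seg[j, 0]
            r = xy[j] - xy[i]
            if abs(det) < tol:
                # near-parallel: degenerate only if the segments nearly touch
                if _segments_close(xy[i], seg[i], xy[j], seg[j], tol):
                    raise DegenerateProjection("near-parallel overlapping edges")
                continue
            t = (r[0] * seg[j, 1] - r[1] * seg[j, 0]) / det
            u = (r[0] * seg[i, 1] - r[1] * seg[i, 0]) / det
            if t < -tol or t > 1 + tol or u < -tol or u > 1 + tol:
                continue
            if min(t, 1 - t) < tol or min(u, 1 - u) < tol:
                raise DegenerateProjection("crossing at a vertex image")
            zi = depth[i] + t * (depth[(i + 1) % n] - depth[i])
            zj = depth[j] + u * (depth[(j + 1) % n] - depth[j])
            if abs(zi - zj) < tol:
                raise DegenerateProjection("ambiguous over/under depth")
            i_over = zi > zj
            # right-handed sign: cross product of over tangent with under tangent
            cr = det if i_over else -det
            signs[cid] = 1 if cr > 0 else -1
            passages.append((i, t, cid, i_over))
            passages.append((j, u, cid, not i_over))
            cid += 1
    passages.sort(key=lambda rec: (rec[0], rec[1]))
    for (ea, ta, *_), (eb, tb, *_) in zip(passages, passages[1:]):
        if ea == eb and abs(ta - tb) < tol:
            raise DegenerateProjection("near-coincident crossings on one edge")
    code = tuple((c, over) for _, _, c, over in passages)
    return KnotDiagram(code, signs)


def _segments_close(p, dp, q, dq, tol):
    """Distance between 2D segments below tol (used only near-parallel)."""
    best = np.inf
    for a, da, b, db in ((p, dp, q, dq), (q, dq, p, dp)):
        for endpoint in (b, b + db):
            w = endpoint - a
            L2 = da @ da
            s = np.clip((w @ da) / L2, 0.0, 1.0) if L2 > 0 else 0.0
            best = min(best, float(np.linalg.norm(w - s * da)))
    return best < tol


def simplify_gauss(D: KnotDiagram) -> KnotDiagram:
    """Reduce the Gauss code by Reidemeister I and II until no rule fires.

    R1 removes a crossing whose two passages are cyclically adjacent (an empty
    kink); R2 removes a pair of crossings that are adjacent on both strands
    with one strand passing over at both.  Both patterns bound empty faces of
    the diagram, so the knot type is preserved.
    """
    code = list(D.code)
    signs = dict(D.signs)
    changed = True
    while changed and code:
        changed = False
        m = len(code)
        pos = {}
        for k, (cid, over) in enumerate(code):
            pos.setdefault(cid, []).append(k)
        # R1: the two passages of one crossing are cyclically adjacent
        for cid, (a, b) in pos.items():
            if b - a == 1 or (a == 0 and b == m - 1):
                code = [entry for entry in code if entry[0] != cid]
                signs.pop(cid, None)
                changed = True
                break
        if changed:
            continue
        # R2: adjacent pair with equal flags whose partners are also adjacent
        for k in range(m):
            (x, fx), (y, fy) = code[k], code[(k + 1) % m]
            if x == y or fx != fy:
                continue
            ox = [q for q in pos[x] if q != k][0]
            oy = [q for q in pos[y] if q != (k + 1) % m][0]
            if (ox - oy) % m == 1 or (oy - ox) % m == 1:
                code = [entry for entry in code if entry[0] not in (x, y)]
                signs.pop(x, None)
                signs.pop(y, None)
                changed = True
                break
    return KnotDiagram(tuple(code), signs)


# ---------------------------------------------------------------------------
# Alexander polynomial
# ---------------------------------------------------------------------------

def _arc_assignment(code):
    """Arc index for every passage; arcs are delimited by under-passages."""
    m = len(code)
    under_pos = [k for k, (_, over) in enumerate(code) if not over]
    c = len(under_pos)
    arc_of_pos = np.empty(m, dtype=int)
    for k in range(m):
        j = np.searchsorted(under_pos, k)  # smallest j with under_pos[j] >= k
        arc_of_pos[k] = j % c
    return arc_of_pos, under_pos


def _alexander_matrix(D: KnotDiagram):
    """Crossing x arc matrix with entries a0 + a1*t, from the crossing relations.

    At a crossing with incoming under-arc i, outgoing under-arc j and over-arc
    k the relation is ``x_j - t x_i + (t - 1) x_k = 0`` for a positive
    crossing and ``t x_j - x_i + (1 - t) x_k = 0`` for a negative one.
    """
    code = D.code
    c = D.n_crossings
    arc_of_pos, under_pos = _arc_assignment(code)
    A0 = np.zeros((c, c), dtype=np.int64)
    A1 = np.zeros((c, c), dtype=np.int64)
    over_pos = {}
    for k, (cid, over) in enumerate(code):
        if over:
            over_pos[cid] = k
    for row, p_under in enumerate(under_pos):
        cid = code[p_under][0]
        arc_in = arc_of_pos[p_under]
        arc_out = (arc_in + 1) % c
        arc_over = arc_of_pos[over_pos[cid]]
        if D.signs[cid] > 0:
            A0[row, arc_out] += 1
            A1[row, arc_in] -= 1
            A1[row, arc_over] += 1
            A0[row, arc_over] -= 1
        else:
            A1[row, arc_out] += 1
            A0[row, arc_in] -= 1
            A0[row, arc_over] += 1
            A1[row, arc_over] -= 1
    return A0, A1


def _det_mod(M: np.ndarray, p: int) -> int:
    """Determinant over Z/p by Gaussian elimination (int64-safe for p < 2^31)."""
    M = np.mod(M, p).astype(np.int64)
    m = M.shape[0]
    if m == 0:
        return 1
    det = 1
    for col in range(m):
        piv = -1
        for r in range(col, m):
            if M[r, col]:
                piv = r
                break
        if piv < 0:
            return 0
        if piv != col:
            M[[col, piv]] = M[[piv, col]]
            det = p - det
        a = int(M[col, col])
        det = det * a % p
        if col + 1 < m:
            inv = pow(a, p - 2, p)
            factors = M[col + 1:, col] * inv % p
            M[col + 1:] = (M[col + 1:] - factors[:, None] * M[col][None, :]) % p
    return det


def _interp_mod(xs, ys, p):
    """Coefficients of the unique polynomial through (xs, ys) over Z/p."""
    k = len(xs)
    master = [1]
    for x in xs:
        nxt = [0] * (len(master) + 1)
        for i, a in enumerate(master):
            nxt[i] = (nxt[i] - x * a) % p
            nxt[i + 1] = (nxt[i + 1] + a) % p
        master = nxt
    coeffs = [0] * k
    for xi, yi in zip(xs, ys):
        # synthetic division of master by (x - xi)
        q = [0] * k
        carry = 0
        for i in range(k, 0, -1):
            carry = (master[i] + xi * carry) % p
            q[i - 1] = carry
        denom = 0
        for i in range(k - 1, -1, -1):
            denom = (denom * xi + q[i]) % p
        w = yi * pow(denom, p - 2, p) % p
        for i in range(k):
            coeffs[i] = (coeffs[i] + w * q[i]) % p
    return coeffs


def _poly_det(A0: np.ndarray, A1: np.ndarray) -> list[int]:
    """Exact determinant of A0 + t*A1 over Z[t].

    Evaluates the determinant at integer points modulo several 31-bit primes,
    interpolates the coefficients in each prime field, and reconstructs the
    integers by CRT, adding primes until the symmetric lift stabilizes.  The
    polynomial's degree is usually far below the matrix size, so the number
    of interpolation points is grown adaptively: a candidate interpolation is
    accepted only if it also reproduces the determinant at two held-out
    evaluation points (in every prime field used).
    """
    m = A0.shape[0]
    if m == 0:
        return [1]
    npts = min(m + 1, 24)
    det_cache: dict[tuple[int, int], int] = {}

    def det_at(p, x):
        if (p, x) not in det_cache:
            det_cache[(p, x)] = _det_mod(A0 + x * A1, p)
        return det_cache[(p, x)]

    def poly_eval(cs, x, p):
        acc = 0
        for c in reversed(cs):
            acc = (acc * x + c) % p
        return acc

    while True:
        xs = list(range(1, npts + 1))
        verify = [npts + 1, npts + 2]
        residues = None
        modulus = 1
        prev_lift = None
        ok = True
        for p in _PRIMES:
            ys = [det_at(p, x) for x in xs]
            cs = _interp_mod(xs, ys, p)
            if any(poly_eval(cs, x, p) != det_at(p, x) for x in verify):
                ok = False  # degree exceeds npts - 1: grow the grid
                break
            if residues is None:
                residues = [c % p for c in cs]
                modulus = p
            else:
                inv = pow(modulus % p, p - 2, p)
                residues = [r + modulus * ((c - r) % p * inv % p)
                            for r, c in zip(residues, cs)]
                modulus *= p
            lift = [r if r <= modulus // 2 else r - modulus for r in residues]
            if prev_lift is not None and lift == prev_lift:
                return lift
            prev_lift = lift
        if ok:
            raise ArithmeticError(
                "Alexander determinant did not stabilize under CRT")
        if npts > m:
            raise ArithmeticError(
                "Alexander determinant interpolation failed on a full grid")
        npts = min(m + 1, 2 * npts)


def alexander_poly(D: KnotDiagram) -> LaurentPoly:
    """Alexander polynomial of a diagram, normalized (min degree 0, value 1 at 1).

    One row and one column of the crossing/arc matrix are deleted and the
    determinant of the remaining integer-polynomial matrix is computed
    exactly.  The empty diagram yields the constant polynomial 1.
    """
    if D.n_crossings == 0:
        return LaurentPoly((1,))
    A0, A1 = _alexander_matrix(D)
    coeffs = _poly_det(A0[:-1, :-1], A1[:-1, :-1])
    return LaurentPoly(coeffs)


def classify(P, n_tries: int = 5,
             rng: np.random.Generator | int | None = None) -> str:
    """Majority-vote knot type over ``n_tries`` generic random projections.

    Each successful projection is simplified and its normalized Alexander
    polynomial looked up in :data:`ALEXANDER_TABLE`; non-matching polynomials
    vote ``"unknown"``.  Ties vote ``"unknown"``.  Degenerate directions are
    retried up to :data:`MAX_DIRECTIONS` draws; if every draw is degenerate a
    :class:`ClassificationFailure` is raised.
    """
    if n_tries < 1:
        raise ValueError("n_tries must be >= 1")
    rng = np.random.default_rng(rng)
    votes: Counter = Counter()
    successes = 0
    for _ in range(MAX_DIRECTIONS):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        try:
            diagram = simplify_gauss(project_to_diagram(P, direction))
            poly = alexander_poly(diagram)
        except (DegenerateProjection, ValueError, ArithmeticError):
            continue
        votes[ALEXANDER_TABLE.get(poly.coeffs, "unknown")] += 1
        successes += 1
        leader, count = votes.most_common(1)[0]
        if count > n_tries // 2:
            return leader
        if successes == n_tries:
            break
    if successes == 0:
        raise ClassificationFailure("all projection directions were degenerate")
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unknown"
    return ranked[0][0]
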