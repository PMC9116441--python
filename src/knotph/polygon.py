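"""Random closed equilateral polygons in 3-space.

A closed equilateral polygon with unit edges is the standard coarse-grained
model of a ring polymer; its number of edges is its length.  Random
conformations are drawn with a crankshaft-rotation Markov chain: a sub-chain
between two randomly chosen vertices is rigidly rotated about the chord
joining them by a uniform angle.  Each move is an isometry of the sub-chain,
so unit edge lengths and closure are preserved exactly; accumulated
floating-point drift is removed by periodic re-equilateralization.

Polygons of a prescribed knot type are obtained by rejection: sample, classify
(see :mod:`knotph.knotid`), keep on match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

EDGE_TOL = 1e-9
#: default number of crankshaft moves per independent sample, times n
BURNIN_FACTOR = 30
#: drift-control period: exact re-equilateralization every this many moves
REPROJECT_EVERY = 1000


class SamplingFailure(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""

    def __init__(self, type_label: str, attempts: int):
        super().__init__(
            f"no polygon of type {type_label!r} found in {attempts} attempts"
        )
        self.type_label = type_label
        self.attempts = attempts


@dataclass(frozen=True)
class PolygonKnot:
    """A closed equilateral polygon: ordered vertices, edge i = (v_i, v_{i+1 mod n}).

    Every edge has length 1 within ``EDGE_TOL``, so the curve length equals
    the number of edges ``n``.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise ValueError("vertices must be an (n>=3, 3) array")
        object.__setattr__(self, "vertices", v)
        lengths = self.edge_lengths()
        if np.max(np.abs(lengths - 1.0)) > EDGE_TOL:
            raise ValueError(
                "polygon is not equilateral with unit edges "
                f"(max deviation {np.max(np.abs(lengths - 1.0)):.3e})"
            )

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        return np.roll(self.vertices, -1, axis=0) - self.vertices

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edges(), axis=1)

    def closure_defect(self) -> float:
        """Norm of the vector sum of the edges (exactly 0 up to rounding)."""
        return float(np.linalg.norm(self.edges().sum(axis=0)))


def regular_polygon(n: int) -> PolygonKnot:
    """Planar regular n-gon with unit edges (the Markov chain's initial state)."""
    if n < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    # circumradius of a unit-edge regular n-gon
    R = 0.5 / np.sin(np.pi / n)
    theta = 2.0 * np.pi * np.arange(n) / n
    verts = np.column_stack([R * np.cos(theta), R * np.sin(theta), np.zeros(n)])
    return PolygonKnot(_equilateralize(verts))


def _rotate_arc(vertices: np.ndarray, i: int, j: int, angle: float) -> np.ndarray:
    """Rotate the vertices cyclically strictly between i and j about chord v_i v_j."""
    v = vertices.copy()
    n = len(v)
    axis = v[j] - v[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("coincident chord endpoints")
    k = axis / norm
    c, s = np.cos(angle), np.sin(angle)
    idx = [(i + m) % n for m in range(1, (j - i) % n)]
    p = v[idx] - v[i]
    # Rodrigues rotation about unit axis k
    rot = p * c + np.cross(k, p) * s + np.outer(p @ k, k) * (1.0 - c)
    v[idx] = rot + v[i]
    return v


def crankshaft_step(P: PolygonKnot, rng: np.random.Generator) -> PolygonKnot:
    """One crankshaft move: rotate a random sub-chain about a random chord.

    The two vertex indices are drawn uniformly (distinct); the rotation angle
    is uniform on [0, 2pi).  Coincident chord endpoints trigger an index
    resample.
    """
    n = P.n
    for _ in range(100):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i == j or (j - i) % n == 1 or (i - j) % n == n - 1:
            # no vertices strictly between, or identical indices
            continue
        if np.linalg.norm(P.vertices[j] - P.vertices[i]) < 1e-12:
            continue
        angle = float(rng.uniform(0.0, 2.0 * np.pi))
        return PolygonKnot(_rotate_arc(P.vertices, i, j, angle))
    raise RuntimeError("could not find a valid crankshaft chord")


@njit(cache=True)
def _splitmix64(state):
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True)
def _equilateralize_nb(v, tol, max_iter):
    n = v.shape[0]
    e = np.empty((n, 3))
    for _ in range(max_iter):
        worst = 0.0
        for i in range(n):
            j = (i + 1) % n
            dx = v[j, 0] - v[i, 0]
            dy = v[j, 1] - v[i, 1]
            dz = v[j, 2] - v[i, 2]
            ln = np.sqrt(dx * dx + dy * dy + dz * dz)
            dev = abs(ln - 1.0)
            if dev > worst:
                worst = dev
            e[i, 0] = dx / ln
            e[i, 1] = dy / ln
            e[i, 2] = dz / ln
        # distribute the closure defect of the normalized edges
        sx = e[:, 0].sum() / n
        sy = e[:, 1].sum() / n
        sz = e[:, 2].sum() / n
        defect = np.sqrt(sx * sx + sy * sy + sz * sz) * n
        if worst < tol and defect < tol:
            break
        for i in range(n):
            e[i, 0] -= sx
            e[i, 1] -= sy
            e[i, 2] -= sz
        for i in range(n - 1):
            v[i + 1, 0] = v[i, 0] + e[i, 0]
            v[i + 1, 1] = v[i, 1] + e[i, 1]
            v[i + 1, 2] = v[i, 2] + e[i, 2]
    return v


def _equilateralize(vertices: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 1000) -> np.ndarray:
    """Project a near-equilateral closed polygon to exact unit edges + closure.

    Alternates normalizing each edge to unit length with distributing the
    resulting closure defect equally over the edges; converges quadratically
    for small perturbations.
    """
    v = np.array(vertices, dtype=float)
    return _equilateralize_nb(v, tol, max_iter)


@njit(cache=True)
def _run_chain(v, n_steps, seed, reproject_every):
    n = v.shape[0]
    state = seed
    for step in range(n_steps):
        # draw a chord with at least one vertex strictly between its endpoints
        while True:
            state, r1 = _splitmix64(state)
            state, r2 = _splitmix64(state)
            i = int(r1 % np.uint64(n))
            j = int(r2 % np.uint64(n))
            if i == j or (j - i) % n == 1 or (i - j) % n == n - 1:
                continue
            ax = v[j, 0] - v[i, 0]
            ay = v[j, 1] - v[i, 1]
            az = v[j, 2] - v[i, 2]
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            if norm < 1e-12:
                continue  # coincident in space: resample indices
            break
        ax /= norm
        ay /= norm
        az /= norm
        state, r3 = _splitmix64(state)
        angle = (r3 >> np.uint64(11)) * (2.0 * np.pi / 9007199254740992.0)
        c = np.cos(angle)
        s = np.sin(angle)
        m = (j - i) % n - 1  # number of vertices strictly between
        for t in range(1, m + 1):
            k = (i + t) % n
            px = v[k, 0] - v[i, 0]
            py = v[k, 1] - v[i, 1]
            pz = v[k, 2] - v[i, 2]
            dot = px * ax + py * ay + pz * az
            cx = ay * pz - az * py
            cy = az * px - ax * pz
            cz = ax * py - ay * px
            v[k, 0] = v[i, 0] + px * c + cx * s + ax * dot * (1.0 - c)
            v[k, 1] = v[i, 1] + py * c + cy * s + ay * dot * (1.0 - c)
            v[k, 2] = v[i, 2] + pz * c + cz * s + az * dot * (1.0 - c)
        if (step + 1) % reproject_every == 0:
            v = _equilateralize_nb(v, 1e-12, 1000)
    return _equilateralize_nb(v, 1e-12, 1000)


def sample_random_polygon(n: int, n_steps: int | None = None,
                          rng: np.random.Generator | int | None = None
                          ) -> PolygonKnot:
    """Draw a random closed equilateral polygon with ``n`` unit edges.

    Runs ``n_steps`` crankshaft moves (default ``30 * n``) from the regular
    n-gon.  The crankshaft chain is ergodic on the space of closed equilateral
    polygons and approximates the uniform distribution on it; exact
    re-equilateralization is applied every ``REPROJECT_EVERY`` moves and at
    the end.  Deterministic for a fixed seed.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if n_steps is None:
        n_steps = BURNIN_FACTOR * n
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(rng)
    seed = np.uint64(rng.integers(0, 2 ** 63, dtype=np.int64))
    v = regular_polygon(n).vertices.copy()
    v = _run_chain(v, n_steps, seed, REPROJECT_EVERY)
    return PolygonKnot(v)


def sample_fixed_type(n: int, type_label: str, max_attempts: int = 1000,
                      rng: np.random.Generator | int | None = None,
                      n_tries: int = 5,
                      return_attempts: bool = False):
    """Rejection-sample a polygon whose classified knot type is ``type_label``.

    Draws independent random polygons and keeps the first one that
    :func:`knotph.knotid.classify` labels as requested.  Raises
    :class:`SamplingFailure` when ``max_attempts`` is exhausted.
    """
    from knotph.knotid import classify, ClassificationFailure, SUPPORTED_TYPES

    if type_label not in SUPPORTED_TYPES and type_label != "unknown":
        raise ValueError(f"unsupported knot type label {type_label!r}")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    rng = np.random.default_rng(rng)
    for attempt in range(1, max_attempts + 1):
        P = sample_random_polygon(n, rng=rng)
        try:
            label = classify(P, n_tries=n_tries, rng=rng)
        except ClassificationFailure:
            continue
        if label == type_label:
            return (P, attempt) if return_attempts else P
    raise SamplingFailure(type_label, max_attempts)
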