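"""Deviation from ideality of a knot embedding, from its Betti curve.

An ideal (ropelength-minimizing) embedding has a characteristic Betti-curve
signature: rank 1 up to the injectivity radius, then a jump to many bars that
die together.  The statistic

    delta_eps = (1/S) * integral_0^S  f_{S,eps}(t) * max(beta1(t) - 1, 0) dt

penalizes excess rank appearing early in the filtration, where
``S = max{t : beta1(t) != 0}`` and the weight ``f_{S,eps}`` decreases
linearly from 1 at t=0 to 0 at ``S - eps`` and vanishes afterwards.  A value
of 0 means the curve never exceeds rank 1 where the weight is positive; large
values mean many early excess classes, i.e. a decidedly non-ideal embedding.

The module also provides the three-member trefoil family (near-ideal
"balanced" torus embedding, elongated torus embedding, nearly planar
"flattened" embedding) used to exercise the ordering
delta(balanced) < delta(elongated) < delta(flattened).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from knotph.polygon import PolygonKnot, _equilateralize
from knotph.ph import BettiCurve

#: default cut-off, one interpolation spacing on the diameter scale
DEFAULT_EPSILON = 0.1


@dataclass(frozen=True)
class IdealityResult:
    S: float
    epsilon: float
    delta: float


class UndefinedSupport(ValueError):
    """The Betti curve is identically zero, so S (and delta) are undefined."""


def support_S(curve: BettiCurve) -> float:
    """End of the support of the Betti curve: largest t with beta1 != 0."""
    nz = np.nonzero(curve.values)[0]
    if len(nz) == 0:
        raise UndefinedSupport("Betti curve is identically zero")
    return float(curve.breakpoints[nz[-1] + 1])


def weight_f(R: float, epsilon: float, t) -> np.ndarray | float:
    """Linear weight: 1 at t=0, 0 at t=R-eps, identically 0 afterwards."""
    if not 0 < epsilon < R:
        raise ValueError("need 0 < epsilon < R")
    t = np.asarray(t, dtype=float)
    w = np.clip(1.0 - t / (R - epsilon), 0.0, 1.0)
    return float(w) if w.ndim == 0 else w


def delta_ideality(curve: BettiCurve, epsilon: float = DEFAULT_EPSILON
                   ) -> IdealityResult:
    """Closed-form evaluation of the deviation-from-ideality statistic.

    The integrand is piecewise linear on the step intervals of the curve, so
    the integral is evaluated exactly, interval by interval; no quadrature.
    """
    S = support_S(curve)
    if not 0 < epsilon < S:
        raise ValueError("need 0 < epsilon < S")
    cut = S - epsilon
    total = 0.0
    bp = curve.breakpoints
    for (lo, hi), val in zip(zip(bp[:-1], bp[1:]), curve.values):
        excess = max(float(val) - 1.0, 0.0)
        if excess == 0.0:
            continue
        a, b = max(lo, 0.0), min(hi, cut)
        if b <= a:
            continue
        # integral of (1 - t/cut) over [a, b]
        total += excess * ((b - a) - (b * b - a * a) / (2.0 * cut))
    return IdealityResult(S=S, epsilon=float(epsilon), delta=total / S)


# ---------------------------------------------------------------------------
# trefoil test family
# ---------------------------------------------------------------------------

_TREFOIL_KINDS = ("balanced", "elongated", "flattened")


def _torus_trefoil(u: np.ndarray, R: float, r: float) -> np.ndarray:
    """(2,3) torus curve on the torus with radii (R, r)."""
    x = (R + r * np.cos(3 * u)) * np.cos(2 * u)
    y = (R + r * np.cos(3 * u)) * np.sin(2 * u)
    z = r * np.sin(3 * u)
    return np.column_stack([x, y, z])


def _resample_equal_arclength(curve: np.ndarray, n: int) -> np.ndarray:
    """Pick n points at equal arclength along a finely sampled closed curve."""
    diffs = np.diff(np.vstack([curve, curve[:1]]), axis=0)
    seglen = np.linalg.norm(diffs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = cum[-1] * np.arange(n) / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (targets - cum[idx]) / seglen[idx]
    ext = np.vstack([curve, curve[:1]])
    return ext[idx] + frac[:, None] * diffs[idx]


def trefoil_family(kind: str, n: int) -> PolygonKnot:
    """Equilateral n-gon approximations of three trefoil embeddings.

    ``balanced``  -- (2,3) torus curve on the (R, r) = (2, 1) torus, the
                     stand-in for a near-ideal embedding;
    ``elongated`` -- the same curve on the (5, 1) torus (longitude much
                     longer than the meridian);
    ``flattened`` -- the balanced curve with its z coordinate scaled by 0.05,
                     close to planar.

    The curve is resampled at equal arclength, equilateralized, and rescaled
    to exactly unit edges.
    """
    if kind not in _TREFOIL_KINDS:
        raise ValueError(f"kind must be one of {_TREFOIL_KINDS}")
    if n < 30:
        raise ValueError("need n >= 30 for a faithful trefoil")
    u = np.linspace(0.0, 2.0 * np.pi, 20000, endpoint=False)
    if kind == "elongated":
        pts = _torus_trefoil(u, 5.0, 1.0)
    else:
        pts = _torus_trefoil(u, 2.0, 1.0)
        if kind == "flattened":
            pts[:, 2] *= 0.05
    verts = _resample_equal_arclength(pts, n)
    verts = verts / np.mean(np.linalg.norm(
        np.diff(np.vstack([verts, verts[:1]]), axis=0), axis=1))
    verts = _equilateralize(verts)
    return PolygonKnot(verts)
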