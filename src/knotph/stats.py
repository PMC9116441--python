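"""Dataset construction and correlation analyses.

Two study designs are provided:

* dataset 1 -- random polygons at a ladder of lengths (full-scale design:
  10^4 per length for lengths 10..100 in steps of 10); every polygon is
  classified and fully featurized.
* dataset 2 -- polygons of fixed knot type obtained by rejection sampling,
  on a ladder of lengths (full-scale design: 10^3 per type for lengths
  50..200 in steps of 50).

Feature rows combine barcode features (I, M, #B, delta_eps) with the
geometric summary; correlations (Pearson and Spearman) are computed per
length group or per type group, with a split-half robustness check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from knotph import geometry, ideality, knotid, ph, polygon

log = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "polygon_id", "length", "label", "I", "M", "num_bars", "S",
    "delta_epsilon",
) + geometry.GeometricSummary.COLUMNS


def polygon_rng(root_seed: int, counter: int) -> np.random.Generator:
    """Independent, reproducible stream for the counter-th polygon of a run."""
    return np.random.default_rng(
        np.random.SeedSequence(root_seed, spawn_key=(counter,)))


def compute_features(P: polygon.PolygonKnot, polygon_id: str,
                     label: str | None = None,
                     samples_per_edge: int = 10,
                     epsilon: float = ideality.DEFAULT_EPSILON,
                     acn_dirs: int = 100,
                     use_spike_filter: bool = False,
                     rng: np.random.Generator | int | None = None,
                     return_curve: bool = False):
    """One feature row for a polygon; classifies it when no label is given."""
    rng = np.random.default_rng(rng)
    if label is None:
        label = knotid.classify(P, rng=rng)
    barcode = ph.rips_h1_barcode(ph.interpolate(P, samples_per_edge))
    if use_spike_filter:
        barcode = ph.spike_filter(barcode)
    curve = ph.betti_curve(barcode)
    try:
        res = ideality.delta_ideality(curve, epsilon)
        S, delta = res.S, res.delta
    except (ideality.UndefinedSupport, ValueError):
        S, delta = np.nan, np.nan
    row = {
        "polygon_id": polygon_id,
        "length": P.n,
        "label": label,
        "I": ph.integral_I(barcode),
        "M": ph.max_bar_M(barcode),
        "num_bars": ph.num_bars_B(barcode),
        "S": S,
        "delta_epsilon": delta,
    }
    row.update(geometry.geometric_summary(P, n_dirs=acn_dirs, rng=rng).as_dict())
    return (row, curve) if return_curve else row


def build_dataset1(lengths, n_per_length: int, seed: int = 0,
                   samples_per_edge: int = 10, acn_dirs: int = 100,
                   use_spike_filter: bool = False,
                   return_curves: bool = False):
    """Random-polygon feature table over a ladder of lengths."""
    if not len(lengths):
        raise ValueError("lengths must be non-empty")
    rows, curves = [], {}
    counter = 0
    for n in lengths:
        for k in range(n_per_length):
            rng = polygon_rng(seed, counter)
            counter += 1
            P = polygon.sample_random_polygon(n, rng=rng)
            pid = f"len{n}_{k}"
            row, curve = compute_features(
                P, pid, samples_per_edge=samples_per_edge,
                acn_dirs=acn_dirs, use_spike_filter=use_spike_filter,
                rng=rng, return_curve=True)
            rows.append(row)
            curves[pid] = curve
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return (df, curves) if return_curves else df


def build_dataset2(types, lengths, n_per_cell: int, seed: int = 0,
                   max_attempts: int = 2000, samples_per_edge: int = 10,
                   acn_dirs: int = 100, use_spike_filter: bool = False,
                   return_curves: bool = False):
    """Fixed-type feature table; incomplete cells are reported, never padded.

    Returns ``(df, incomplete)`` where ``incomplete`` maps (type, length) to
    the number of missing rows for cells whose rejection sampling exhausted
    ``max_attempts`` (with ``curves`` prepended when ``return_curves``).
    """
    rows, curves = [], {}
    incomplete = {}
    counter = 0
    for label in types:
        for n in lengths:
            got = 0
            for k in range(n_per_cell):
                rng = polygon_rng(seed, counter)
                counter += 1
                try:
                    P, attempts = polygon.sample_fixed_type(
                        n, label, max_attempts=max_attempts, rng=rng,
                        return_attempts=True)
                except polygon.SamplingFailure:
                    break
                log.debug("type %s length %d sample %d: %d attempts",
                          label, n, k, attempts)
                pid = f"{label}_len{n}_{k}"
                row, curve = compute_features(
                    P, pid, label=label, samples_per_edge=samples_per_edge,
                    acn_dirs=acn_dirs, use_spike_filter=use_spike_filter,
                    rng=rng, return_curve=True)
                rows.append(row)
                curves[pid] = curve
                got += 1
            if got < n_per_cell:
                incomplete[(label, n)] = n_per_cell - got
                log.warning("cell (%s, %d) incomplete: %d of %d sampled",
                            label, n, got, n_per_cell)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if return_curves:
        return df, curves, incomplete
    return df, incomplete


# ---------------------------------------------------------------------------
# correlations and fits
# ---------------------------------------------------------------------------

def _correlations(table: pd.DataFrame, group_col: str, x: str, y: str
                  ) -> pd.DataFrame:
    recs = []
    for key, sub in table.groupby(group_col):
        if len(sub) < 3:
            log.warning("group %s=%r skipped: only %d records",
                        group_col, key, len(sub))
            continue
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            log.warning("group %s=%r skipped: constant feature", group_col, key)
            continue
        pr = sps.pearsonr(xv, yv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sr = sps.spearmanr(xv, yv)
        recs.append({"group": key, "x": x, "y": y,
                     "pearson": pr.statistic, "pearson_p": pr.pvalue,
                     "spearman": sr.statistic, "spearman_p": sr.pvalue,
                     "n": len(sub)})
    return pd.DataFrame(
        recs, columns=["group", "x", "y", "pearson", "pearson_p",
                       "spearman", "spearman_p", "n"])


def correlations_by_length(table: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    """Pearson and Spearman correlation of features x, y within each length."""
    return _correlations(table, "length", x, y)


def correlations_by_type(table: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    """Pearson and Spearman correlation of features x, y within each knot type."""
    return _correlations(table, "label", x, y)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def linear_fit(x, y) -> LinearFit:
    """Least-squares line; constant y is flagged degenerate with R^2 = 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(y) == 0:
        return LinearFit(0.0, float(np.mean(y)), 0.0, degenerate=True)
    res = sps.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2))


def average_summaries(table: pd.DataFrame, curves: dict,
                      by=("label", "length")):
    """Per-cell mean I, mean Betti-curve maximum, and the averaged curve.

    Returns (summary DataFrame, {cell: average BettiCurve}).
    """
    recs = {}
    avg_curves = {}
    for key, sub in table.groupby(list(by)):
        cell_curves = [curves[pid] for pid in sub["polygon_id"] if pid in curves]
        if not cell_curves:
            continue
        avg = ph.average_betti_curve(cell_curves)
        avg_curves[key] = avg
        maxima = [ph.curve_max(curves[pid])[1] for pid in sub["polygon_id"]
                  if pid in curves]
        recs[key] = {
            **dict(zip(by, key)),
            "mean_I": float(sub["I"].mean()),
            "mean_curve_max": float(np.mean(maxima)),
            "n": len(sub),
        }
    df = pd.DataFrame(list(recs.values()),
                      columns=list(by) + ["mean_I", "mean_curve_max", "n"])
    return df, avg_curves


def split_half_robustness(table: pd.DataFrame, x: str, y: str,
                          group_col: str = "length",
                          seed: int = 0):
    """Random halving of the table; per-group correlations on each half.

    Returns (correlations on half A, on half B, max |Pearson difference|
    over the groups present in both halves).
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(table), dtype=bool)
    mask[rng.permutation(len(table))[: len(table) // 2]] = True
    ca = _correlations(table[mask], group_col, x, y)
    cb = _correlations(table[~mask], group_col, x, y)
    merged = ca.merge(cb, on="group", suffixes=("_a", "_b"))
    max_dr = (float(np.max(np.abs(merged["pearson_a"] - merged["pearson_b"])))
              if len(merged) else np.nan)
    return ca, cb, max_dr
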