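"""Coordinate file I/O, run configuration, and the end-to-end pipeline.

Coordinates are stored as plain text, either XYZ-style (one ``x y z`` line
per vertex) or CSV with an ``x,y,z`` header, at 17 significant digits so a
write/read round trip is bit-exact.  Multi-polygon batches use a CSV with a
``polygon_id`` column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from knotph.polygon import PolygonKnot, _equilateralize

log = logging.getLogger(__name__)

_FMT = "%.17g"


class CoordinateParseError(ValueError):
    """A coordinate file row could not be parsed; carries the line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def write_coords(P: PolygonKnot, path) -> None:
    """Write vertices as XYZ (default) or CSV when the suffix is .csv."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        header = "x,y,z"
        np.savetxt(path, P.vertices, fmt=_FMT, delimiter=",",
                   header=header, comments="")
    else:
        np.savetxt(path, P.vertices, fmt=_FMT, delimiter=" ")


def read_coords(path, renormalize: bool = False, tol: float = 1e-6
                ) -> PolygonKnot:
    """Read a polygon from an XYZ or CSV coordinate file.

    The polygon must be equilateral with unit edges within ``tol``; with
    ``renormalize`` the vertices are projected to exact unit edges instead of
    raising.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1 and any(p.lower() in ("x", "y", "z") for p in parts):
                continue  # CSV header
            if len(parts) != 3:
                raise CoordinateParseError(
                    path, lineno, f"expected 3 numbers, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise CoordinateParseError(path, lineno, str(exc)) from exc
    if len(rows) < 3:
        raise CoordinateParseError(path, len(rows), "need at least 3 vertices")
    verts = np.array(rows)
    lengths = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)
    dev = float(np.max(np.abs(lengths - 1.0)))
    if dev > tol:
        if not renormalize:
            raise ValueError(
                f"{path}: polygon is not equilateral with unit edges "
                f"(max deviation {dev:.3e}); pass renormalize=True to project")
        verts = verts / np.mean(lengths)
    if renormalize or dev > 1e-9:
        verts = _equilateralize(verts)
    return PolygonKnot(verts)


def write_batch(polygons: dict, path) -> None:
    """Write {polygon_id: PolygonKnot} as one CSV with a polygon_id column."""
    frames = []
    for pid, P in polygons.items():
        df = pd.DataFrame(P.vertices, columns=["x", "y", "z"])
        df.insert(0, "polygon_id", pid)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format=_FMT)


def read_batch(path) -> dict:
    """Read a multi-polygon CSV back into {polygon_id: PolygonKnot}."""
    df = pd.read_csv(path)
    out = {}
    for pid, sub in df.groupby("polygon_id", sort=False):
        verts = _equilateralize(sub[["x", "y", "z"]].to_numpy(float))
        out[str(pid)] = PolygonKnot(verts)
    return out


def barcodes_to_frame(barcodes: dict) -> pd.DataFrame:
    """{polygon_id: Barcode} -> tidy frame (polygon_id, dim, birth, death)."""
    recs = []
    for pid, bc in barcodes.items():
        for birth, death in bc.intervals:
            recs.append({"polygon_id": pid, "dim": 1,
                         "birth": birth, "death": death})
    return pd.DataFrame(recs, columns=["polygon_id", "dim", "birth", "death"])


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run depends on; a run is a pure function of this."""

    seed: int = 0
    lengths: tuple = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    n_per_length: int = 200
    types: tuple = ("0_1", "3_1", "4_1")
    type_lengths: tuple = (50, 100, 150, 200)
    n_per_cell: int = 50
    max_attempts: int = 2000
    samples_per_edge: int = 10
    epsilon: float = 0.1
    acn_dirs: int = 100
    use_spike_filter: bool = False
    spike_birth_lo: float = 0.10
    spike_birth_hi: float = 0.13
    spike_max_persistence: float = 0.05
    out_dir: str = "knotph_out"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in data.items()})
        cfg.validate()
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    def validate(self) -> None:
        from knotph.knotid import SUPPORTED_TYPES
        for t in self.types:
            if t not in SUPPORTED_TYPES and t != "unknown":
                raise ValueError(f"unknown knot type label in config: {t!r}")
        if not self.lengths or not self.type_lengths:
            raise ValueError("lengths must be non-empty")


def run_pipeline(config: RunConfig, which: str = "both") -> Path:
    """Run dataset construction + correlations; write CSV artifacts.

    Produces ``features1.csv``/``features2.csv``, the per-length and per-type
    correlation CSVs, and ``run.log`` (including rejection counts for typed
    sampling).  Deterministic for a fixed config.
    """
    from knotph import stats

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setLevel(logging.DEBUG)
    root = logging.getLogger("knotph")
    root.addHandler(handler)
    root.setLevel(logging.DEBUG)
    try:
        if which in ("both", "pipeline1"):
            df1 = stats.build_dataset1(
                config.lengths, config.n_per_length, seed=config.seed,
                samples_per_edge=config.samples_per_edge,
                acn_dirs=config.acn_dirs,
                use_spike_filter=config.use_spike_filter)
            df1.to_csv(out / "features1.csv", index=False)
            pieces = []
            for y in ("V_hull", "V_sphere", "Rg", "acn", "curv_total"):
                pieces.append(stats.correlations_by_length(df1, "I", y))
                pieces.append(stats.correlations_by_length(df1, "M", y))
            pd.concat(pieces).to_csv(out / "correlations_by_length.csv",
                                     index=False)
        if which in ("both", "pipeline2"):
            df2, incomplete = stats.build_dataset2(
                config.types, config.type_lengths, config.n_per_cell,
                seed=config.seed, max_attempts=config.max_attempts,
                samples_per_edge=config.samples_per_edge,
                acn_dirs=config.acn_dirs,
                use_spike_filter=config.use_spike_filter)
            df2.to_csv(out / "features2.csv", index=False)
            for cell, missing in incomplete.items():
                log.warning("incomplete cell %s: %d missing", cell, missing)
            pieces = []
            for y in ("V_hull", "V_sphere", "Rg", "acn"):
                pieces.append(stats.correlations_by_type(df2, "I", y))
            pd.concat(pieces).to_csv(out / "correlations_by_type.csv",
                                     index=False)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
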