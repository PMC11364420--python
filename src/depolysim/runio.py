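"""Deterministic output writing and fixture generation.

Every run writes a tidy time-series CSV, a metrics JSON, the resolved
configuration and a manifest with SHA-256 checksums, so outputs are
byte-reproducible for a given configuration and seed (floating point
formatting is pinned).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import KineticParams, MetabolicParams, SpatialConfig, ValidationError
from .pbe import init_pool
from .spatial import Grid

__all__ = ["write_outputs", "generate_fixtures", "RunRecord"]

FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


@dataclasses.dataclass
class RunRecord:
    """Manifest of one simulation run."""

    config: dict
    seed: int | None
    outputs: dict[str, str]   #: filename -> sha256


def write_outputs(
    result,
    outdir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    stem: str = "result",
) -> RunRecord:
    """Write time series, metrics, resolved config and manifest.

    ``result`` is any object with ``timeseries`` (DataFrame), ``metrics``
    and ``params`` attributes (ScenarioResult or SpatialResult).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    ts_path = outdir / f"{stem}_timeseries.csv"
    if result is not None and getattr(result, "timeseries", None) is not None:
        result.timeseries.to_csv(ts_path, index=False, float_format=FLOAT_FMT)
        files[ts_path.name] = _sha256(ts_path)

    if result is not None:
        metrics_path = outdir / f"{stem}_metrics.json"
        with open(metrics_path, "w") as fh:
            json.dump(_jsonable(result.metrics), fh, indent=2, sort_keys=True)
            fh.write("\n")
        files[metrics_path.name] = _sha256(metrics_path)

    summary = getattr(result, "summary", None)
    if summary is not None:
        sum_path = outdir / f"{stem}_summary.csv"
        summary.to_csv(sum_path, index=False, float_format=FLOAT_FMT)
        files[sum_path.name] = _sha256(sum_path)

    snaps = getattr(result, "snapshots", None)
    if snaps:
        rows = []
        for t, field in snaps:
            ny, nx = field.shape
            iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
            rows.append(pd.DataFrame({
                "time_h": t, "y": iy.ravel(), "x": ix.ravel(),
                "C_b": field.ravel(),
            }))
        snap_path = outdir / f"{stem}_snapshots.csv"
        pd.concat(rows, ignore_index=True).to_csv(
            snap_path, index=False, float_format=FLOAT_FMT)
        files[snap_path.name] = _sha256(snap_path)

    cfg = config if config is not None else (result.params if result is not None else {})
    cfg_path = outdir / f"{stem}_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(_jsonable(cfg), fh, sort_keys=True)
    files[cfg_path.name] = _sha256(cfg_path)

    record = RunRecord(config=_jsonable(cfg), seed=seed, outputs=files)
    manifest_path = outdir / f"{stem}_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(dataclasses.asdict(record), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return record


def pool_frame(M: float, n: int) -> pd.DataFrame:
    pool = init_pool(M, n)
    nz = pool.N > 0
    return pd.DataFrame({
        "size_class": pool.sizes[nz],
        "concentration_nmol_per_mm3": pool.N[nz],
    })


def grid_frame(grid: Grid) -> pd.DataFrame:
    """Site table of a lattice state (polymer totals, not full spectra)."""
    ny, nx = grid.occupant.shape
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    sizes = np.arange(1, grid.N.shape[0] + 1, dtype=float)
    poly = np.tensordot(sizes, grid.N, axes=1)
    return pd.DataFrame({
        "y": iy.ravel(),
        "x": ix.ravel(),
        "occupant": grid.occupant.ravel(),
        "C_b": grid.C_b.ravel(),
        "E_exo": grid.E_exo.ravel(),
        "E_endo": grid.E_endo.ravel(),
        "N_1": grid.N[0].ravel(),
        "polymer_C": poly.ravel(),
        "DIN": grid.DIN.ravel(),
    })


def generate_fixtures(kind: str, params: dict, seed: int, outdir: str | Path) -> list[Path]:
    """Write deterministic initial-state files used as standing test inputs.

    Kinds: ``pool`` (monodisperse polymer pool), ``grid`` (single-taxon
    lattice), ``consortium_grid`` (two-specialist lattice).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "pool":
        M, n = params.get("M", 300.0), params.get("n", 200)
        path = outdir / f"pool_M{M:g}_n{n}.csv"
        pool_frame(M, n).to_csv(path, index=False, float_format=FLOAT_FMT)
        written.append(path)
    elif kind in ("grid", "consortium_grid"):
        if kind == "grid":
            taxa = [MetabolicParams(fr_exo=params.get("fr_exo", 1.0))]
        else:
            taxa = [MetabolicParams(fr_exo=1.0), MetabolicParams(fr_exo=0.0)]
        cfg = SpatialConfig(
            nx=params.get("nx", 30), ny=params.get("ny", 30),
            dt=params.get("dt", 0.1),
        )
        grid = Grid.initialize(
            cfg, KineticParams(), taxa,
            M=params.get("M", 150.0), n=params.get("n", 500), seed=seed,
            colonists_per_taxon=params.get("colonists_per_taxon", 4),
        )
        path = outdir / f"{kind}_M{params.get('M', 150.0):g}_seed{seed}.csv"
        grid_frame(grid).to_csv(path, index=False, float_format=FLOAT_FMT)
        written.append(path)
    else:
        raise ValidationError(f"unknown fixture kind {kind!r}")
    return written
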