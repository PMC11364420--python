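"""Scenario drivers and summary metrics.

Four study designs are wrapped here:

* enzyme-only degradation of a monodisperse pool by a fixed enzyme mix;
* well-mixed microbial growth of a single taxon on such a pool;
* scans of the exo fraction ``fr_exo`` of a fixed total enzyme pool,
  scoring each mix by its total degradation time ``T_deg`` (synergy);
* niche maps of maximum biomass / survival over substrate mass and
  ``fr_exo`` grids.

Time series are returned as tidy pandas DataFrames; derived metrics
(``T_deg``, maximum biomass, survival) are recomputable from them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd

from .params import KineticParams, MetabolicParams, ValidationError
from .pbe import EnzymePool, PBETrajectory, degradation_time, init_pool, integrate_pbe
from .microbe import WellMixedState, wellmixed_step

__all__ = [
    "ScenarioResult",
    "GrowthConfig",
    "run_enzyme_only",
    "run_wellmixed",
    "scan_frexo_degradation",
    "niche_map",
]


@dataclass
class ScenarioResult:
    """Resolved parameters, tidy time series and derived metrics of one run.

    ``summary`` optionally carries a compact per-sample table (e.g. the
    monomer/total-mass curve of a degradation run).
    """

    params: dict[str, Any]
    timeseries: pd.DataFrame
    metrics: dict[str, Any]
    summary: pd.DataFrame | None = None


@dataclass
class GrowthConfig:
    """Initial state and run settings of a well-mixed growth simulation.

    The population is seeded with a small enzyme pool (split according to
    its ``fr_exo`` trait) to bootstrap degradation; it then either becomes
    self-sustaining or dies out.
    """

    M: float = 300.0
    n: int = 500
    C_b0: float = 10.0
    E_seed: float = 1.0
    DIN0: float = 200.0
    N1_seed: float = 0.0
    t_end: float = 400.0
    dt: float = 0.1
    record_every: float = 1.0
    #: survival = genuine growth: max(C_b) >= survival_factor * C_b0.  In a
    #: closed microcosm successful populations always starve after exhausting
    #: the pool, so aliveness at t_end is reported but not part of the criterion.
    survival_factor: float = 2.0
    #: stop early once the population is dead (metrics are then settled)
    stop_when_dead: bool = True

    def __post_init__(self) -> None:
        if self.M <= 0 or self.n < 1:
            raise ValidationError("substrate requires M > 0 and n >= 1")
        if self.C_b0 < 0 or self.E_seed < 0 or self.DIN0 < 0 or self.N1_seed < 0:
            raise ValidationError("initial amounts must be >= 0")
        if self.t_end <= 0 or self.dt <= 0:
            raise ValidationError("t_end and dt must be > 0")


def run_enzyme_only(
    M: float,
    n: int,
    E_exo: float,
    E_endo: float,
    kin: KineticParams | None = None,
    t_end: float = 5000.0,
    eps: float = 1e-3,
    **integrate_kwargs,
) -> ScenarioResult:
    """Degrade a monodisperse pool with a constant enzyme mix.

    No microbes, no enzyme decay: the classical fixed-enzyme degradation
    experiment.  Returns the size-spectrum time series and ``T_deg``.
    """
    kin = kin or KineticParams()
    pool = init_pool(M, n)
    enz = EnzymePool(E_exo=E_exo, E_endo=E_endo)
    traj = integrate_pbe(pool, enz, kin, t_end=t_end, eps=eps, **integrate_kwargs)
    t_deg = degradation_time(traj)
    ts = _spectrum_frame(traj)
    params = {
        "M": M, "n": n, "E_exo": E_exo, "E_endo": E_endo,
        "k_exo": kin.k_exo, "k_endo": kin.k_endo, "km": kin.km,
        "t_end": t_end, "eps": eps,
    }
    metrics = {
        "T_deg": t_deg,
        "degraded": math.isfinite(t_deg),
        "final_monomers": float(traj.monomers[-1]),
    }
    target = (1.0 - eps) * traj.M0
    summary = pd.DataFrame({
        "time_h": traj.t,
        "monomers": traj.monomers,
        "total_mass": traj.total_mass,
        "T_deg_flag": traj.monomers >= target,
    })
    return ScenarioResult(params=params, timeseries=ts, metrics=metrics, summary=summary)


def _spectrum_frame(traj: PBETrajectory) -> pd.DataFrame:
    """Tidy (time_h, size_class, concentration) table, zero classes dropped."""
    rows = []
    sizes = np.arange(1, traj.N.shape[1] + 1)
    for k, t in enumerate(traj.t):
        nz = traj.N[k] > 0
        rows.append(pd.DataFrame({
            "time_h": t,
            "size_class": sizes[nz],
            "concentration_nmol_per_mm3": traj.N[k][nz],
        }))
    return pd.concat(rows, ignore_index=True)


def run_wellmixed(
    metab: MetabolicParams,
    kin: KineticParams | None = None,
    config: GrowthConfig | None = None,
) -> ScenarioResult:
    """Simulate one taxon growing on a polymer pool in well-mixed conditions."""
    kin = kin or KineticParams()
    cfg = config or GrowthConfig()
    pool = init_pool(cfg.M, cfg.n)
    N = pool.N
    N[0] += cfg.N1_seed
    state = WellMixedState(
        N=N,
        E_exo=metab.fr_exo * cfg.E_seed,
        E_endo=(1.0 - metab.fr_exo) * cfg.E_seed,
        C_b=cfg.C_b0,
        DIN=cfg.DIN0,
    )
    M_total = cfg.M + cfg.N1_seed
    target = (1.0 - 1e-3) * M_total

    n_steps = int(round(cfg.t_end / cfg.dt))
    rec_stride = max(int(round(cfg.record_every / cfg.dt)), 1)
    rows = []
    max_Cb = state.C_b
    t_deg = math.inf

    def record():
        rows.append((
            state.t, state.C_b, state.E_exo, state.E_endo,
            float(state.N[0]), state.DIN, state.ledger.respiration_C,
        ))

    record()
    for step in range(1, n_steps + 1):
        wellmixed_step(state, metab, kin, cfg.dt)
        max_Cb = max(max_Cb, state.C_b)
        if math.isinf(t_deg):
            # completion: free monomers plus already-consumed carbon cover the pool
            sizes = np.arange(1, state.N.size + 1)
            consumed = M_total - float(sizes @ state.N)
            if float(state.N[0]) + consumed >= target:
                t_deg = state.t
        if step % rec_stride == 0:
            record()
        if cfg.stop_when_dead and not state.alive:
            record()
            break

    ts = pd.DataFrame(
        rows,
        columns=["time_h", "C_b", "E_exo", "E_endo", "N_1", "DIN", "cum_respiration"],
    )
    survived = bool(max_Cb >= cfg.survival_factor * cfg.C_b0)
    params = {
        "fr_exo": metab.fr_exo, "M": cfg.M, "n": cfg.n, "C_b0": cfg.C_b0,
        "E_seed": cfg.E_seed, "DIN0": cfg.DIN0, "t_end": cfg.t_end, "dt": cfg.dt,
        "k_exo": kin.k_exo, "k_endo": kin.k_endo, "km": kin.km,
    }
    metrics = {
        "max_biomass": float(max_Cb),
        "survived": survived,
        "alive_at_end": bool(state.alive),
        "T_deg": t_deg,
        "final_C_b": float(state.C_b),
    }
    return ScenarioResult(params=params, timeseries=ts, metrics=metrics)


def scan_frexo_degradation(
    M: float,
    n: int,
    E_total: float = 3.0,
    kin: KineticParams | None = None,
    frexo_grid=None,
    t_end: float = 5000.0,
    eps: float = 1e-3,
) -> ScenarioResult:
    """T_deg of a fixed total enzyme pool split between exo and endo.

    ``E_exo = fr * E_total`` and ``E_endo = (1-fr) * E_total`` for each
    ``fr`` on the grid (default 0 to 1 in steps of 0.05).  Mixes that do
    not finish within ``t_end`` are flagged and excluded from the argmin;
    ties break toward the smaller ``fr_exo``.
    """
    kin = kin or KineticParams()
    if frexo_grid is None:
        frexo_grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    frexo_grid = np.asarray(frexo_grid, dtype=float)

    t_degs = []
    for fr in frexo_grid:
        res = run_enzyme_only(
            M, n, E_exo=fr * E_total, E_endo=(1.0 - fr) * E_total,
            kin=kin, t_end=t_end, eps=eps,
        )
        t_degs.append(res.metrics["T_deg"])
    t_degs = np.asarray(t_degs)
    finite = np.isfinite(t_degs)
    if finite.any():
        argmin_fr = float(frexo_grid[finite][int(np.argmin(t_degs[finite]))])
    else:
        argmin_fr = math.nan
    ts = pd.DataFrame({"fr_exo": frexo_grid, "T_deg": t_degs, "degraded": finite})
    params = {
        "M": M, "n": n, "E_total": E_total,
        "k_exo": kin.k_exo, "k_endo": kin.k_endo, "km": kin.km,
        "t_end": t_end, "eps": eps,
    }
    metrics = {
        "argmin_frexo": argmin_fr,
        "min_T_deg": float(np.min(t_degs[finite])) if finite.any() else math.inf,
        "grid_step": float(np.min(np.diff(np.sort(frexo_grid)))) if frexo_grid.size > 1 else math.nan,
    }
    return ScenarioResult(params=params, timeseries=ts, metrics=metrics)


def niche_map(
    M_grid,
    frexo_grid,
    metab: MetabolicParams | None = None,
    kin: KineticParams | None = None,
    config: GrowthConfig | None = None,
) -> ScenarioResult:
    """Maximum biomass and survival over (M, fr_exo) in well-mixed runs.

    The time series table holds one row per grid cell; the metrics carry
    the survival matrix (rows M, columns fr_exo) as nested lists.
    """
    metab = metab or MetabolicParams()
    kin = kin or KineticParams()
    cfg = config or GrowthConfig()
    M_grid = np.asarray(M_grid, dtype=float)
    frexo_grid = np.asarray(frexo_grid, dtype=float)

    rows = []
    for M in M_grid:
        for fr in frexo_grid:
            res = run_wellmixed(
                replace(metab, fr_exo=float(fr)), kin, replace(cfg, M=float(M)),
            )
            rows.append({
                "M": float(M),
                "fr_exo": float(fr),
                "max_biomass": res.metrics["max_biomass"],
                "survived": res.metrics["survived"],
                "alive_at_end": res.metrics["alive_at_end"],
                "T_deg": res.metrics["T_deg"],
            })
    table = pd.DataFrame(rows)
    surv = table.pivot(index="M", columns="fr_exo", values="survived")
    maxb = table.pivot(index="M", columns="fr_exo", values="max_biomass")
    params = {
        "M_grid": [float(x) for x in M_grid],
        "frexo_grid": [float(x) for x in frexo_grid],
        "growth": vars(cfg).copy(),
        "k_exo": kin.k_exo, "k_endo": kin.k_endo,
    }
    metrics = {
        "survival_matrix": surv.to_numpy().tolist(),
        "max_biomass_matrix": maxb.to_numpy().tolist(),
    }
    return ScenarioResult(params=params, timeseries=table, metrics=metrics)
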