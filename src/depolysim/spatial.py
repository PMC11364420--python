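"""Spatially explicit individual-based model on a microsite lattice.

Each microsite of an ``ny x nx`` lattice (default 100 x 100 at 10 um
spacing, i.e. 1 mm^2) holds at most one microbial taxon together with its
wall-attached enzymes, a local polymer size spectrum and a local DIN
pool.  Within a site everything is well mixed and follows the same
fragmentation + stoichiometric growth step as the zero-dimensional model;
between sites, soluble oligomers (sizes up to ``soluble_max``) diffuse
with the Rouse-Zimm scaling ``D_i = D_0 / i`` on a 5-point stencil with
no-flux boundaries.  Populations spread by splitting their biomass in
half into a random empty neighbor once they exceed a division threshold;
random mortality empties sites together with their enzymes.

State is stored in dense arrays (size classes x ny x nx for the polymers)
and the reaction step is evaluated only on occupied sites, so sparse
colonies cost little.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .params import KineticParams, MetabolicParams, SpatialConfig, ValidationError
from .pbe import fragmentation_step
from .microbe import ConservationLedger, partition_metabolism, uptake

__all__ = [
    "Grid",
    "size_dependent_diffusivity",
    "diffuse_step",
    "divide_and_colonize",
    "random_mortality",
    "spatial_step",
    "run_spatial",
    "diffusive_loss_experiment",
    "consortium_run",
    "SpatialResult",
]

EMPTY = -1


def size_dependent_diffusivity(i: int, cfg: SpatialConfig) -> float:
    """Oligomer diffusivity, um^2/h: D_0 * i^(-1/x), zero above soluble_max."""
    if i < 1:
        raise ValidationError("oligomer size must be >= 1")
    if i > cfg.soluble_max:
        return 0.0
    return cfg.D_0 * float(i) ** (-1.0 / cfg.x)


@dataclass
class Grid:
    """Dense lattice state plus seeded random substreams.

    Substreams (placement, division, mortality) are spawned from one root
    seed so that disabling one stochastic process does not shift the
    draws of the others.
    """

    cfg: SpatialConfig
    kin: KineticParams
    taxa: list[MetabolicParams]
    N: np.ndarray                      #: (n_max, ny, nx) size-class concentrations
    DIN: np.ndarray                    #: (ny, nx)
    C_b: np.ndarray                    #: (ny, nx) biomass carbon
    E_exo: np.ndarray                  #: (ny, nx)
    E_endo: np.ndarray                 #: (ny, nx)
    occupant: np.ndarray               #: (ny, nx) int, taxon index or EMPTY
    t: float = 0.0
    ledger: ConservationLedger = field(default_factory=ConservationLedger)
    rng_division: np.random.Generator = None
    rng_mortality: np.random.Generator = None
    rng_placement: np.random.Generator = None

    @classmethod
    def initialize(
        cls,
        cfg: SpatialConfig,
        kin: KineticParams,
        taxa: list[MetabolicParams],
        M: float,
        n: int,
        seed: int,
        colonists_per_taxon: int = 4,
        C_b0: float = 10.0,
        E_seed: float = 1.0,
        DIN0: float = 200.0,
    ) -> "Grid":
        """Uniform substrate, DIN and randomly placed colonists.

        Colonist sites are drawn without replacement from the whole
        lattice and assigned to taxa in round-robin order, giving equal
        counts and spatial interleaving.  Each colonist starts with
        ``C_b0`` biomass and ``E_seed`` enzyme carbon split by its
        ``fr_exo`` trait.
        """
        if M <= 0 or n < 1:
            raise ValidationError("substrate requires M > 0 and n >= 1")
        ss = np.random.SeedSequence(seed)
        s_place, s_div, s_mort = ss.spawn(3)
        rng_placement = np.random.default_rng(s_place)

        ny, nx = cfg.ny, cfg.nx
        N = np.zeros((n, ny, nx))
        N[n - 1] = M / n
        DIN = np.full((ny, nx), float(DIN0))
        C_b = np.zeros((ny, nx))
        E_exo = np.zeros((ny, nx))
        E_endo = np.zeros((ny, nx))
        occupant = np.full((ny, nx), EMPTY, dtype=np.int64)

        total = colonists_per_taxon * len(taxa)
        if total > ny * nx:
            raise ValidationError("more colonists than lattice sites")
        flat = rng_placement.choice(ny * nx, size=total, replace=False)
        for k, pos in enumerate(flat):
            tx = k % len(taxa)
            iy, ix = divmod(int(pos), nx)
            occupant[iy, ix] = tx
            C_b[iy, ix] = C_b0
            E_exo[iy, ix] = taxa[tx].fr_exo * E_seed
            E_endo[iy, ix] = (1.0 - taxa[tx].fr_exo) * E_seed

        return cls(
            cfg=cfg, kin=kin, taxa=list(taxa),
            N=N, DIN=DIN, C_b=C_b, E_exo=E_exo, E_endo=E_endo,
            occupant=occupant,
            rng_division=np.random.default_rng(s_div),
            rng_mortality=np.random.default_rng(s_mort),
            rng_placement=rng_placement,
        )

    # --- conservation audit -------------------------------------------------
    def total_carbon(self) -> float:
        sizes = np.arange(1, self.N.shape[0] + 1, dtype=float)
        poly = float(np.tensordot(sizes, self.N, axes=1).sum())
        return (
            poly
            + float(self.C_b.sum())
            + float(self.E_exo.sum() + self.E_endo.sum())
            + self.ledger.respiration_C
            + self.ledger.death_C
            + self.ledger.enzyme_decay_C
        )

    def total_nitrogen(self) -> float:
        cn_m = np.array([p.CN_m for p in self.taxa])
        cn_e = np.array([p.CN_e for p in self.taxa])
        occ = self.occupant >= 0
        bio_N = float((self.C_b[occ] / cn_m[self.occupant[occ]]).sum())
        # enzymes may outlive nothing (they die with their producer), so the
        # occupant's CN_e applies wherever enzymes are present
        enz = self.E_exo + self.E_endo
        enz_N = float((enz[occ] / cn_e[self.occupant[occ]]).sum())
        return (
            float(self.DIN.sum())
            + bio_N
            + enz_N
            + self.ledger.death_N
            + self.ledger.enzyme_decay_N
        )

    def biomass_by_taxon(self) -> np.ndarray:
        out = np.zeros(len(self.taxa))
        for tx in range(len(self.taxa)):
            out[tx] = float(self.C_b[self.occupant == tx].sum())
        return out


def _laplacian(field: np.ndarray) -> np.ndarray:
    """5-point discrete Laplacian with no-flux (reflecting) boundaries."""
    padded = np.pad(field, 1, mode="edge")
    return (
        padded[:-2, 1:-1] + padded[2:, 1:-1]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * field
    )


def diffuse_step(grid: Grid, dt: float | None = None) -> None:
    """Explicit diffusion of soluble size classes (and optionally DIN).

    Per-class totals are conserved exactly up to round-off; insoluble
    classes (above ``soluble_max``) never move.
    """
    cfg = grid.cfg
    if dt is None:
        dt = cfg.dt
    if cfg.D_0 == 0.0:
        return
    if dt > cfg.cfl_limit + 1e-12:
        raise ValidationError("diffusion step exceeds the stability bound")
    h2 = cfg.h**2
    top = min(cfg.soluble_max, grid.N.shape[0])
    for c in range(top):
        D = size_dependent_diffusivity(c + 1, cfg)
        if D == 0.0:
            continue
        grid.N[c] += (D * dt / h2) * _laplacian(grid.N[c])
    if cfg.din_diffuses:
        grid.DIN += (cfg.D_0 * dt / h2) * _laplacian(grid.DIN)


_NEIGH4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGH8 = _NEIGH4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def divide_and_colonize(grid: Grid, dt: float | None = None) -> int:
    """Split over-threshold populations into a random empty neighbor.

    Half of the biomass and half of each enzyme pool move with the
    daughter (enzymes are wall-attached).  Sites with no empty neighbor
    do not divide.  The sweep order is randomized each call; returns the
    number of divisions performed.
    """
    cfg = grid.cfg
    rng = grid.rng_division
    neigh = _NEIGH4 if cfg.neighborhood == 4 else _NEIGH8
    ny, nx = grid.occupant.shape
    candidates = np.argwhere((grid.occupant >= 0) & (grid.C_b > cfg.division_threshold))
    if candidates.size == 0:
        return 0
    rng.shuffle(candidates, axis=0)
    n_div = 0
    for iy, ix in candidates:
        empties = [
            (iy + dy, ix + dx)
            for dy, dx in neigh
            if 0 <= iy + dy < ny and 0 <= ix + dx < nx
            and grid.occupant[iy + dy, ix + dx] == EMPTY
        ]
        if not empties:
            continue
        jy, jx = empties[int(rng.integers(len(empties)))]
        grid.occupant[jy, jx] = grid.occupant[iy, ix]
        for arr in (grid.C_b, grid.E_exo, grid.E_endo):
            half = 0.5 * arr[iy, ix]
            arr[iy, ix] = half
            arr[jy, jx] += half
        n_div += 1
    return n_div


def random_mortality(grid: Grid, dt: float | None = None) -> int:
    """Independent random death of occupied sites.

    Death removes the biomass and the site's enzymes (they are attached
    to the dying cells); both are recorded in the conservation ledger.
    Returns the number of deaths.
    """
    cfg = grid.cfg
    if dt is None:
        dt = cfg.dt
    p_death = min(cfg.death_rate * dt, 1.0)
    if p_death == 0.0:
        return 0
    occ = grid.occupant >= 0
    draws = grid.rng_mortality.random(grid.occupant.shape)
    dying = occ & (draws < p_death)
    if not dying.any():
        return 0
    cn_m = np.array([p.CN_m for p in grid.taxa])
    cn_e = np.array([p.CN_e for p in grid.taxa])
    tx = grid.occupant[dying]
    enz = grid.E_exo[dying] + grid.E_endo[dying]
    grid.ledger.death_C += float(grid.C_b[dying].sum())
    grid.ledger.death_N += float((grid.C_b[dying] / cn_m[tx]).sum())
    grid.ledger.enzyme_decay_C += float(enz.sum())
    grid.ledger.enzyme_decay_N += float((enz / cn_e[tx]).sum())
    grid.C_b[dying] = 0.0
    grid.E_exo[dying] = 0.0
    grid.E_endo[dying] = 0.0
    grid.occupant[dying] = EMPTY
    return int(dying.sum())


def _reaction_step(grid: Grid, dt: float) -> None:
    """Local well-mixed chemistry and growth at every occupied site."""
    occ_mask = grid.occupant >= 0
    if not occ_mask.any():
        return
    iy, ix = np.nonzero(occ_mask)
    tx = grid.occupant[iy, ix]
    N_loc = grid.N[:, iy, ix]                 # (n, S) view copy
    E_x = grid.E_exo[iy, ix]
    E_n = grid.E_endo[iy, ix]
    C_b = grid.C_b[iy, ix]
    DIN = grid.DIN[iy, ix]

    # taxa share kinetic constants; enzymes differ only in concentration
    N_loc = fragmentation_step(N_loc, E_x, E_n, grid.kin, dt)

    # per-taxon metabolic parameters, vectorized over sites
    out_Cb = C_b.copy()
    out_DIN = DIN.copy()
    out_Ex = E_x.copy()
    out_En = E_n.copy()
    for t_idx, p in enumerate(grid.taxa):
        sel = tx == t_idx
        if not sel.any():
            continue
        C_up, N_up = uptake(N_loc[0, sel], DIN[sel], C_b[sel], p, dt)
        N_loc[0, sel] -= C_up
        rec = partition_metabolism(C_up, N_up, C_b[sel], p, dt)
        out_Cb[sel] = C_b[sel] + rec.C_growth - rec.C_drawn_from_biomass
        # N bound in biomass catabolized for maintenance is eliminated to DIN
        out_DIN[sel] = DIN[sel] - N_up + rec.N_to_DIN + rec.C_drawn_from_biomass / p.CN_m
        grid.ledger.respiration_C += float(np.sum(rec.C_maintenance + rec.C_respired))
        out_Ex[sel] = E_x[sel] + p.fr_exo * rec.C_enzyme
        out_En[sel] = E_n[sel] + (1.0 - p.fr_exo) * rec.C_enzyme
        # exponential enzyme decay
        decay = 1.0 - math.exp(-p.r_e * dt)
        lost_x = out_Ex[sel] * decay
        lost_n = out_En[sel] * decay
        out_Ex[sel] -= lost_x
        out_En[sel] -= lost_n
        grid.ledger.enzyme_decay_C += float(np.sum(lost_x + lost_n))
        grid.ledger.enzyme_decay_N += float(np.sum(lost_x + lost_n)) / p.CN_e
        # death below minimum biomass: site emptied, enzymes die with it
        dead = out_Cb[sel] < p.C_min
        if dead.any():
            idx_sel = np.nonzero(sel)[0][dead]
            grid.ledger.death_C += float(out_Cb[idx_sel].sum())
            grid.ledger.death_N += float(out_Cb[idx_sel].sum()) / p.CN_m
            grid.ledger.enzyme_decay_C += float((out_Ex[idx_sel] + out_En[idx_sel]).sum())
            grid.ledger.enzyme_decay_N += float((out_Ex[idx_sel] + out_En[idx_sel]).sum()) / p.CN_e
            out_Cb[idx_sel] = 0.0
            out_Ex[idx_sel] = 0.0
            out_En[idx_sel] = 0.0
            grid.occupant[iy[idx_sel], ix[idx_sel]] = EMPTY

    grid.N[:, iy, ix] = N_loc
    grid.C_b[iy, ix] = out_Cb
    grid.DIN[iy, ix] = out_DIN
    grid.E_exo[iy, ix] = out_Ex
    grid.E_endo[iy, ix] = out_En


def spatial_step(grid: Grid, enable_division: bool = True, enable_mortality: bool = True) -> None:
    """One operator-split lattice step.

    Order: local reactions (fragmentation, uptake, metabolism, enzyme
    turnover, death) -> diffusion of soluble classes -> division and
    colonization -> random mortality.
    """
    dt = grid.cfg.dt
    _reaction_step(grid, dt)
    diffuse_step(grid, dt)
    if enable_division:
        divide_and_colonize(grid, dt)
    if enable_mortality:
        random_mortality(grid, dt)
    grid.t += dt


@dataclass
class SpatialResult:
    """Per-taxon biomass time series, snapshots and summary metrics."""

    params: dict[str, Any]
    timeseries: pd.DataFrame
    metrics: dict[str, Any]
    snapshots: list[tuple[float, np.ndarray]] = field(default_factory=list)


def run_spatial(
    grid: Grid,
    t_end: float,
    record_every: float = 5.0,
    snapshot_every: float | None = None,
    enable_division: bool = True,
    enable_mortality: bool = True,
) -> SpatialResult:
    """Advance a grid to ``t_end`` recording per-taxon aggregates."""
    dt = grid.cfg.dt
    n_steps = int(round(t_end / dt))
    stride = max(int(round(record_every / dt)), 1)
    snap_stride = None
    if snapshot_every is not None:
        snap_stride = max(int(round(snapshot_every / dt)), 1)

    n_taxa = len(grid.taxa)
    rows = []
    snaps: list[tuple[float, np.ndarray]] = []
    max_Cb_total = float(grid.C_b.sum())

    def record():
        bio = grid.biomass_by_taxon()
        occ_counts = [int((grid.occupant == tx).sum()) for tx in range(n_taxa)]
        rows.append(
            (grid.t, *bio, *occ_counts,
             float(grid.E_exo.sum()), float(grid.E_endo.sum()),
             float(grid.N[0].sum()), float(grid.DIN.sum()),
             grid.ledger.respiration_C)
        )

    record()
    for step in range(1, n_steps + 1):
        spatial_step(grid, enable_division, enable_mortality)
        max_Cb_total = max(max_Cb_total, float(grid.C_b.sum()))
        if step % stride == 0:
            record()
        if snap_stride is not None and step % snap_stride == 0:
            snaps.append((grid.t, grid.C_b.copy()))

    cols = (
        ["time_h"]
        + [f"C_b_taxon{tx}" for tx in range(n_taxa)]
        + [f"sites_taxon{tx}" for tx in range(n_taxa)]
        + ["E_exo", "E_endo", "N_1", "DIN", "cum_respiration"]
    )
    ts = pd.DataFrame(rows, columns=cols)
    bio_final = grid.biomass_by_taxon()
    metrics = {
        "max_total_biomass": max_Cb_total,
        "final_biomass_by_taxon": bio_final.tolist(),
        "final_sites_by_taxon": [int((grid.occupant == tx).sum()) for tx in range(n_taxa)],
    }
    params = {
        "t_end": t_end,
        "grid": (grid.cfg.ny, grid.cfg.nx),
        "dt": dt,
        "D_0": grid.cfg.D_0,
        "taxa_fr_exo": [p.fr_exo for p in grid.taxa],
    }
    return SpatialResult(params=params, timeseries=ts, metrics=metrics, snapshots=snaps)


def diffusive_loss_experiment(
    fr_exo: float,
    M: float,
    n: int = 500,
    D_0: float = 30.0,
    cfg: SpatialConfig | None = None,
    metab: MetabolicParams | None = None,
    kin: KineticParams | None = None,
    t_end: float = 400.0,
    seed: int = 0,
    **grid_kwargs,
) -> dict[str, float]:
    """Biomass penalty of oligomer diffusion for a lone, non-dividing cell.

    Runs a single occupied central microsite twice — with ``D_0 = 0`` and
    with the requested ``D_0`` — division and mortality disabled, and
    returns ``max(C_b | D_0) / max(C_b | 0)`` together with both maxima.
    """
    base = cfg or SpatialConfig(nx=15, ny=15)
    metab = metab or MetabolicParams()
    metab = type(metab)(**{**vars(metab), "fr_exo": fr_exo})
    kin = kin or KineticParams()

    maxima = {}
    for D in (0.0, D_0):
        cfg_D = SpatialConfig(**{**vars(base), "D_0": D})
        grid = Grid.initialize(
            cfg_D, kin, [metab], M=M, n=n, seed=seed,
            colonists_per_taxon=1, **grid_kwargs,
        )
        # relocate the lone colonist to the center for symmetry
        iy, ix = np.nonzero(grid.occupant >= 0)
        cy, cx = cfg_D.ny // 2, cfg_D.nx // 2
        for arr in (grid.C_b, grid.E_exo, grid.E_endo):
            arr[cy, cx] = arr[iy[0], ix[0]]
            if (iy[0], ix[0]) != (cy, cx):
                arr[iy[0], ix[0]] = 0.0
        grid.occupant[:] = EMPTY
        grid.occupant[cy, cx] = 0
        res = run_spatial(
            grid, t_end=t_end, record_every=t_end,
            enable_division=False, enable_mortality=False,
        )
        # the lone site is the only population: track its max biomass
        maxima[D] = res.metrics["max_total_biomass"]
    ratio = maxima[D_0] / maxima[0.0] if maxima[0.0] > 0 else math.nan
    return {"ratio": ratio, "max_Cb_no_diffusion": maxima[0.0], "max_Cb_diffusion": maxima[D_0]}


def consortium_run(
    M: float,
    n: int = 500,
    cfg: SpatialConfig | None = None,
    kin: KineticParams | None = None,
    base_metab: MetabolicParams | None = None,
    t_end: float = 400.0,
    seed: int = 0,
    colonists_per_taxon: int = 8,
    extinction_share: float = 0.01,
    record_every: float = 10.0,
    **grid_kwargs,
) -> SpatialResult:
    """Two-specialist consortium (exo taxon 0, endo taxon 1) on one lattice.

    Equal numbers of interleaved colonists of an exo specialist
    (``fr_exo = 1``) and an endo specialist (``fr_exo = 0``) compete for
    one polymer pool.  The outcome label compares final biomass shares:
    a taxon below ``extinction_share`` of the total is extinct; both
    above means coexistence; nobody alive means collapse.
    """
    cfg = cfg or SpatialConfig()
    kin = kin or KineticParams()
    base = base_metab or MetabolicParams()
    exo_taxon = type(base)(**{**vars(base), "fr_exo": 1.0})
    endo_taxon = type(base)(**{**vars(base), "fr_exo": 0.0})
    grid = Grid.initialize(
        cfg, kin, [exo_taxon, endo_taxon], M=M, n=n, seed=seed,
        colonists_per_taxon=colonists_per_taxon, **grid_kwargs,
    )
    res = run_spatial(grid, t_end=t_end, record_every=record_every)
    bio = np.asarray(res.metrics["final_biomass_by_taxon"])
    total = bio.sum()
    if total <= 0:
        outcome = "collapse"
    else:
        share = bio / total
        exo_alive = share[0] >= extinction_share
        endo_alive = share[1] >= extinction_share
        if exo_alive and endo_alive:
            outcome = "coexistence"
        elif exo_alive:
            outcome = "exo_dominance"
        elif endo_alive:
            outcome = "endo_dominance"
        else:
            outcome = "collapse"
    res.metrics["outcome"] = outcome
    res.metrics["final_share"] = (bio / total).tolist() if total > 0 else [0.0, 0.0]
    res.params.update({"M": M, "n": n, "seed": seed})
    return res
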