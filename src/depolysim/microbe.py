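"""Stoichiometric C:N growth model of a depolymerizing microbe.

Each time step the metabolism is processed in a fixed order: monomer and
DIN uptake, maintenance, enzyme production (split between exo and endo
enzyme by the trait ``fr_exo``), growth, and death below a minimum
biomass.  Growth and enzyme production respire fixed fractions of their
carbon flux; carbon that can find no stoichiometric partner is respired
and surplus nitrogen is returned to the DIN pool, so the per-step carbon
and nitrogen budgets close exactly.

All flux helpers are written against numpy ufuncs and accept scalars or
arrays of microsites; the well-mixed driver simply calls them with
scalars.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import KineticParams, MetabolicParams, ValidationError
from .pbe import fragmentation_step

__all__ = [
    "MicrobeState",
    "DINPool",
    "BudgetRecord",
    "ConservationLedger",
    "uptake",
    "partition_metabolism",
    "produce_enzymes",
    "enzyme_decay",
    "death_check",
    "WellMixedState",
    "wellmixed_step",
]


@dataclass
class MicrobeState:
    """Biomass carbon of a single population (one microsite or well-mixed)."""

    C_b: float
    alive: bool = True
    taxon_id: int = 0

    def __post_init__(self) -> None:
        if self.C_b < 0:
            raise ValidationError("biomass C_b must be >= 0")


@dataclass
class DINPool:
    DIN: float = 0.0

    def __post_init__(self) -> None:
        if self.DIN < 0:
            raise ValidationError("DIN must be >= 0")


@dataclass
class BudgetRecord:
    """Per-step mass fluxes; closes carbon and nitrogen exactly.

    C:  C_uptake + C_drawn_from_biomass
          = C_maintenance + C_enzyme + C_growth + C_respired
    N:  N_uptake = N_enzyme + N_growth + N_to_DIN
    ``C_respired`` excludes maintenance, which is reported separately
    (total CO2 of the step is C_maintenance + C_respired).
    """

    C_uptake: float = 0.0
    N_uptake: float = 0.0
    C_maintenance: float = 0.0
    C_drawn_from_biomass: float = 0.0
    C_enzyme: float = 0.0
    N_enzyme: float = 0.0
    C_growth: float = 0.0
    N_growth: float = 0.0
    C_respired: float = 0.0
    N_to_DIN: float = 0.0

    def carbon_closure(self) -> float:
        """Signed residual of the carbon budget (zero when closed)."""
        inflow = self.C_uptake + self.C_drawn_from_biomass
        outflow = self.C_maintenance + self.C_enzyme + self.C_growth + self.C_respired
        return inflow - outflow

    def nitrogen_closure(self) -> float:
        return self.N_uptake - (self.N_enzyme + self.N_growth + self.N_to_DIN)


def uptake(N_1, DIN, C_b, p: MetabolicParams, dt: float):
    """Monomer-C and DIN uptake over ``dt``, capped at pool availability.

    Demand follows surface-limited Michaelis-Menten kinetics,
    ``V_u * C_b^a_u * X / (K_u + X)``, applied independently to the
    monomer and DIN pools.
    """
    if dt < 0:
        raise ValidationError("dt must be >= 0")
    N_1 = np.maximum(N_1, 0.0)
    DIN = np.maximum(DIN, 0.0)
    area = p.V_u * np.asarray(C_b, dtype=float) ** p.a_u
    C_up = np.minimum(area * N_1 / (p.K_u + N_1) * dt, N_1)
    N_up = np.minimum(area * DIN / (p.K_u + DIN) * dt, DIN)
    return C_up, N_up


def partition_metabolism(C_uptake, N_uptake, C_b, p: MetabolicParams, dt: float) -> BudgetRecord:
    """Split the step's uptake into maintenance, enzymes, growth, waste.

    Order of precedence: (1) maintenance ``m*C_b*dt`` is paid from uptake
    first, any deficit drawn from biomass; (2) a fraction ``f_e`` of the
    post-maintenance carbon is offered to enzyme synthesis, of which
    ``1-gamma_e`` becomes enzyme and requires N at C:N = CN_e — if N is
    short the allocation scales down and the unspent carbon joins the
    growth pool; (3) growth converts the remaining carbon at efficiency
    ``1-gamma_g`` under C:N = CN_m, N-limited the same way; (4) leftover
    carbon is respired, leftover nitrogen returns to DIN.
    """
    C_uptake = np.maximum(np.asarray(C_uptake, dtype=float), 0.0)
    N_uptake = np.maximum(np.asarray(N_uptake, dtype=float), 0.0)
    C_b = np.asarray(C_b, dtype=float)

    maint_demand = p.m * C_b * dt
    paid_from_uptake = np.minimum(C_uptake, maint_demand)
    drawn = np.minimum(maint_demand - paid_from_uptake, C_b)
    maintenance = paid_from_uptake + drawn

    C_after = C_uptake - paid_from_uptake
    C_alloc = p.f_e * C_after
    enz_struct = (1.0 - p.gamma_e) * C_alloc
    enz_N = enz_struct / p.CN_e
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(enz_N > 0, np.minimum(1.0, N_uptake / np.where(enz_N > 0, enz_N, 1.0)), 1.0)
    enz_struct = enz_struct * scale
    enz_N = enz_N * scale
    C_alloc_used = enz_struct / (1.0 - p.gamma_e) if p.gamma_e < 1.0 else enz_struct * 0.0
    enz_resp = C_alloc_used - enz_struct

    growth_pool = C_after - C_alloc_used
    N_remaining = N_uptake - enz_N
    g_struct = np.minimum((1.0 - p.gamma_g) * growth_pool, N_remaining * p.CN_m)
    g_used = g_struct / (1.0 - p.gamma_g) if p.gamma_g < 1.0 else g_struct * 0.0
    g_resp = g_used - g_struct
    leftover_C = growth_pool - g_used
    g_N = g_struct / p.CN_m

    return BudgetRecord(
        C_uptake=C_uptake,
        N_uptake=N_uptake,
        C_maintenance=maintenance,
        C_drawn_from_biomass=drawn,
        C_enzyme=enz_struct,
        N_enzyme=enz_N,
        C_growth=g_struct,
        N_growth=g_N,
        C_respired=enz_resp + g_resp + leftover_C,
        N_to_DIN=N_uptake - enz_N - g_N,
    )


def produce_enzymes(C_enzyme_structural, fr_exo):
    """Split structural enzyme carbon between the two enzyme pools."""
    fr = np.asarray(fr_exo, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValidationError("fr_exo must lie in [0, 1]")
    return fr * C_enzyme_structural, (1.0 - fr) * C_enzyme_structural


def enzyme_decay(E, r_e: float, dt: float):
    """Exact exponential decay of an enzyme pool over ``dt``."""
    if dt < 0:
        raise ValidationError("dt must be >= 0")
    return E * np.exp(-r_e * dt)


def death_check(state: MicrobeState, p: MetabolicParams) -> MicrobeState:
    """Kill populations below the minimum viable biomass (inclusive bound)."""
    if state.alive and state.C_b < p.C_min:
        return MicrobeState(C_b=0.0, alive=False, taxon_id=state.taxon_id)
    return state


@dataclass
class ConservationLedger:
    """Cumulative sinks needed to audit closed C and N balances."""

    respiration_C: float = 0.0
    death_C: float = 0.0
    death_N: float = 0.0
    enzyme_decay_C: float = 0.0
    enzyme_decay_N: float = 0.0


@dataclass
class WellMixedState:
    """Full state of a zero-dimensional (well-mixed) simulation."""

    N: np.ndarray                 #: polymer size-class concentrations
    E_exo: float
    E_endo: float
    C_b: float
    DIN: float
    alive: bool = True
    t: float = 0.0
    ledger: ConservationLedger = field(default_factory=ConservationLedger)

    def total_carbon(self) -> float:
        sizes = np.arange(1, self.N.size + 1)
        return float(
            sizes @ self.N
            + self.C_b
            + self.E_exo
            + self.E_endo
            + self.ledger.respiration_C
            + self.ledger.death_C
            + self.ledger.enzyme_decay_C
        )

    def total_nitrogen(self, p: MetabolicParams) -> float:
        return float(
            self.DIN
            + self.C_b / p.CN_m
            + (self.E_exo + self.E_endo) / p.CN_e
            + self.ledger.death_N
            + self.ledger.enzyme_decay_N
        )


def wellmixed_step(
    state: WellMixedState,
    p: MetabolicParams,
    kin: KineticParams,
    dt: float,
) -> BudgetRecord:
    """Advance a well-mixed system by ``dt`` in place.

    Operator-split order: fragmentation -> uptake -> metabolic partition
    -> enzyme production and decay -> death check.
    """
    state.N = fragmentation_step(state.N, state.E_exo, state.E_endo, kin, dt)

    if state.alive and state.C_b > 0.0:
        C_up, N_up = uptake(state.N[0], state.DIN, state.C_b, p, dt)
        state.N[0] -= C_up
        state.DIN -= N_up
        rec = partition_metabolism(C_up, N_up, state.C_b, p, dt)
        state.C_b += float(rec.C_growth - rec.C_drawn_from_biomass)
        # N bound in biomass catabolized for maintenance is eliminated to DIN
        state.DIN += float(rec.N_to_DIN + rec.C_drawn_from_biomass / p.CN_m)
        state.ledger.respiration_C += float(rec.C_maintenance + rec.C_respired)
        dE_exo, dE_endo = produce_enzymes(float(rec.C_enzyme), p.fr_exo)
        state.E_exo += float(dE_exo)
        state.E_endo += float(dE_endo)
    else:
        rec = BudgetRecord()

    for attr in ("E_exo", "E_endo"):
        before = getattr(state, attr)
        after = float(enzyme_decay(before, p.r_e, dt))
        setattr(state, attr, after)
        state.ledger.enzyme_decay_C += before - after
        state.ledger.enzyme_decay_N += (before - after) / p.CN_e

    if state.alive and state.C_b < p.C_min:
        state.ledger.death_C += state.C_b
        state.ledger.death_N += state.C_b / p.CN_m
        state.C_b = 0.0
        state.alive = False

    state.t += dt
    return rec
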