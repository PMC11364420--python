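"""Parameter containers shared across the model.

All concentrations are in nmol per mm^3 (monomer-carbon equivalents: one
polymerized unit carries one nmol C per nmol), rates in per hour.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields


class ValidationError(ValueError):
    """A parameter or configuration value is out of its admissible range."""


@dataclass
class KineticParams:
    """Michaelis-Menten constants of the two depolymerase classes.

    k_exo, k_endo : turnover numbers, nmol nmol C^-1 h^-1.  k_exo counts
        end-cleaving events per enzyme carbon; k_endo counts internal
        scission events per enzyme carbon.
    km : shared half-saturation constant, nmol/mm^3.
    exo_denominator_includes_monomers : if True the exo saturation term sums
        all size classes including free monomers; the default excludes
        monomers, which are not an exo substrate, so that the monomer
        release rate stays constant while the chain count does.
    """

    k_exo: float = 0.82
    k_endo: float = 0.82
    km: float = 0.5
    exo_denominator_includes_monomers: bool = False

    def __post_init__(self) -> None:
        if self.k_exo < 0 or self.k_endo < 0:
            raise ValidationError("turnover numbers k_exo/k_endo must be >= 0")
        if self.km <= 0:
            raise ValidationError("half-saturation km must be > 0")


@dataclass
class MetabolicParams:
    """Stoichiometric growth-model parameters of one microbial taxon.

    The trait under study is ``fr_exo``: the fraction of enzyme synthesis
    allocated to the exo-enzyme (1 = exo specialist, 0 = endo specialist).
    The remaining parameters describe a generic heterotroph with fixed
    biomass and enzyme C:N ratios; they are shared by all taxa so that
    specialists differ in nothing but their enzyme portfolio.
    """

    fr_exo: float = 1.0
    #: maximum uptake rate coefficient, h^-1 (nmol C)^(1-a_u)
    V_u: float = 1.0
    #: surface scaling of uptake with biomass (sphere area ~ volume^(2/3))
    a_u: float = 2.0 / 3.0
    #: uptake half-saturation, nmol/mm^3
    K_u: float = 0.5
    #: specific maintenance rate, h^-1
    m: float = 0.05
    #: fraction of post-maintenance uptake carbon allocated to enzyme production
    f_e: float = 0.1
    #: respired fraction of the growth flux
    gamma_g: float = 0.25
    #: respired fraction of the enzyme-production flux
    gamma_e: float = 0.25
    #: biomass C:N ratio
    CN_m: float = 8.0
    #: enzyme C:N ratio
    CN_e: float = 3.0
    #: first-order enzyme decay rate, h^-1
    r_e: float = 0.002
    #: death threshold, nmol C per microsite
    C_min: float = 0.08

    def __post_init__(self) -> None:
        for name in ("fr_exo", "f_e", "gamma_g", "gamma_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v!r} must lie in [0, 1]")
        for name in ("V_u", "a_u", "K_u", "m", "r_e", "C_min"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.CN_m <= 0 or self.CN_e <= 0:
            raise ValidationError("C:N ratios must be > 0")
        if self.K_u == 0:
            raise ValidationError("K_u must be > 0")


@dataclass
class SpatialConfig:
    """Lattice geometry, transport and demographic settings.

    The default lattice is 100 x 100 microsites at 10 um spacing (1 mm^2).
    Oligomers up to ``soluble_max`` units diffuse with the Rouse-Zimm
    scaling D_i = D_0 * i^(-1/x); larger chains are insoluble.
    """

    nx: int = 100
    ny: int = 100
    #: lattice spacing, um
    h: float = 10.0
    #: monomer diffusivity, um^2/h
    D_0: float = 30.0
    #: Rouse-Zimm exponent
    x: float = 1.0
    #: largest diffusing oligomer size
    soluble_max: int = 10
    #: per-site per-hour death probability rate
    death_rate: float = 1e-4
    #: biomass triggering division, nmol C
    division_threshold: float = 20.0
    #: 4 (von Neumann) or 8 (Moore) connectivity for colonization
    neighborhood: int = 4
    din_diffuses: bool = False
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValidationError("grid dimensions must be positive")
        if self.h <= 0 or self.D_0 < 0 or self.x <= 0:
            raise ValidationError("h must be > 0, D_0 >= 0, x > 0")
        if self.soluble_max < 1:
            raise ValidationError("soluble_max must be >= 1")
        if not 0.0 <= self.death_rate:
            raise ValidationError("death_rate must be >= 0")
        if self.neighborhood not in (4, 8):
            raise ValidationError("neighborhood must be 4 or 8")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.D_0 > 0 and self.dt > self.cfl_limit + 1e-12:
            raise ValidationError(
                f"dt={self.dt} violates the diffusion stability bound "
                f"dt <= h^2/(4 D_0) = {self.cfl_limit:.4g} h"
            )

    @property
    def cfl_limit(self) -> float:
        """Largest stable explicit-diffusion step, h^2/(4 D_0)."""
        if self.D_0 == 0:
            return float("inf")
        return self.h**2 / (4.0 * self.D_0)


def asdict_shallow(obj) -> dict:
    """Shallow dataclass -> dict (no recursion into nested dataclasses)."""
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
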