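# Methods

This note documents the model equations, the numerical choices, the
default parameters and what the simulations do and do not show.  All
concentrations are in nmol per mm³ of monomer-carbon equivalents (one
polymerized unit ≡ 1 nmol C per nmol); time is in hours.

## Fragmentation dynamics (population balance)

The polymer pool is a vector `N_1..N_n` of chain-length classes.  The
exo (end-cleaving) kernel removes one terminal monomer per event:

    i-chain  →  (i−1)-chain + monomer          rate v_exo_i

with `v_exo_i = k_exo E_exo N_i / (k_m + Σ_{j≥2} N_j)`.  The saturation
term sums *chains only* (j ≥ 2): free monomers are not an exo substrate,
and excluding them is what makes the monomer release rate constant while
the chain count is constant — the defining kinetic signature of the
end-cleaver.  A config switch (`exo_denominator_includes_monomers`)
restores the alternative reading, in which release slows as monomers
accumulate.

The endo (random-scission) kernel cuts any bond with equal probability:

    i-chain  →  j-chain + (i−j)-chain,  j uniform on 1..i−1

with class rate `v_endo_i = k_endo (i−1) E_endo N_i / (k_m + Σ_j (j−1) N_j)`.
Each cut of an i-chain adds `2 v_endo_i/(i−1)` to every class below i;
the gains are evaluated with suffix sums, so one right-hand-side call is
O(n) rather than O(n²).  Both kernels conserve `Σ i·N_i` identically;
exo on a dimer produces two monomers in a single event (one event = one
bond cut throughout), which also makes exo and endo dynamics coincide
exactly on dimer-only pools at equal turnover numbers — a useful
cross-check exercised in the test suite.

Defaults: `k_exo = 0.82 nmol (nmol C)⁻¹ h⁻¹`, `k_m = 0.5 nmol/mm³`;
`k_endo` equals `k_exo` or half of it depending on the scenario.

### Integration

Well-mixed enzyme-only runs use adaptive Runge–Kutta (`solve_ivp`,
rtol 1e−8, atol 1e−12).  Runge–Kutta steps preserve linear invariants,
so mass is conserved to round-off; the integrator additionally audits
the trajectory and fails loudly above 1e−6 relative drift.  Completion
is located by a terminal event on `N_1 ≥ (1−ε)·M` with ε = 1e−3 (99.9 %
conversion), the operational definition of the total degradation time
`T_deg`; runs that do not complete report `T_deg = ∞` rather than raise.

Coupled (growth and lattice) runs use a fixed-step explicit update.  To
keep it positivity-preserving, the combined event rate of each source
class is throttled so a class loses at most 90 % of its content per
step; loss and gains scale together, so conservation stays exact while
the overshoot oscillations of a plain Euler step in nearly-empty classes
are eliminated.  Values in (−1e−12, 0) are clipped to zero; anything
more negative aborts the step.

A caveat worth knowing: because the deterministic cascade lets chains
complete over a spread of ~√(n) events, the measured `T_deg` of an
exo-only run exceeds the naive constant-rate estimate (bonds ÷ release
rate) by a few percent at ε = 1e−3 — the last ~0.5 % of mass sits in the
dispersive tail.  The estimate is accurate to ~1 % only down to ε ≈ 1e−2.

### Stochastic oracle

An event-driven (Gillespie) simulation of integer molecule counts
implements the same two kernels and serves as an independent check: the
ensemble mean converges to the PBE solution, and the first endo cut of
an n-chain yields fragment sizes uniform on {1..n−1}.  It is restricted
to small systems (≤10⁴ molecules, n ≤ 50) and is never used as the
production integrator.

## Microbial growth

One population per (well-mixed volume or microsite), biomass carbon
`C_b`, with fixed stoichiometry (biomass C:N = `CN_m`, enzymes `CN_e`).
Each step, in order:

1. **Uptake** of monomers and dissolved inorganic nitrogen (DIN),
   `V_u · C_b^{a_u} · X/(K_u + X) · dt`, capped at the pool content.
   `a_u = 2/3` encodes surface-limited transport (area ∝ volume^{2/3}).
2. **Maintenance** `m·C_b·dt`, paid from uptake first; any deficit is
   catabolized from biomass (this is what lets starving populations
   shrink and die), with the liberated nitrogen returned to DIN.
3. **Enzyme production**: a fraction `f_e` of post-maintenance carbon,
   of which `1−γ_e` becomes enzyme (needing N at `CN_e`) and `γ_e` is
   respired; allocation scales down to the N-limited level if needed.
   Production splits between the two enzymes by the trait `fr_exo`.
4. **Growth** from the remaining C and N at `CN_m`, efficiency `1−γ_g`.
5. Leftover carbon is respired, leftover nitrogen returns to DIN; the
   per-step carbon and nitrogen budgets close to machine precision
   (property-tested), and whole runs carry explicit sink ledgers
   (respiration, dead biomass, decayed enzymes) audited to ≤1e−6.
6. **Enzyme decay** `E ← E·exp(−r_e dt)` (exact for the linear term) and
   **death** when `C_b < C_min`; dead biomass and (on the lattice) the
   dead cell's wall-attached enzymes leave the modeled pools.  No
   necromass recycling — the simplest closure.

### Default parameters and how they were fixed

The growth sub-model's constants are not identifiable from first
principles here, so they are package defaults chosen once so that the
model's qualitative regime structure is realized, then frozen:

| parameter | value | meaning |
|---|---|---|
| `V_u` | 1.0 h⁻¹ (nmol C)^{1/3} | uptake rate coefficient |
| `a_u` | 2/3 | surface scaling of uptake |
| `K_u` | 0.5 nmol/mm³ | uptake half-saturation |
| `m` | 0.05 h⁻¹ | specific maintenance |
| `f_e` | 0.1 | enzyme allocation fraction |
| `γ_g`, `γ_e` | 0.25 | respired fractions |
| `CN_m`, `CN_e` | 8, 3 | biomass / enzyme C:N |
| `r_e` | 0.002 h⁻¹ | enzyme decay |
| `C_min` | 0.08 nmol C | death threshold |
| `C_b0` | 10 nmol C | initial (colonist) biomass |
| `E_seed` | 1.0 nmol C/mm³ | seed enzymes at initialization |
| `DIN₀` | 200 nmol N/mm³ | initial DIN (non-limiting) |

The constants trade off against each other tightly.  The exo
specialist must starve on chain-poor pools, which pins `m·C_b0` between
the seed-enzyme release rates at low and high substrate
(0.31·E_seed < m·C_b0 < 0.70·E_seed at the reference chain lengths);
the endo specialist's niche edge is the race between its fragmentation
lag (∝ M / (k·E)) and the starvation horizon (ln(C_b0/C_min)/m); and
enzyme production must outrun decay once growth starts (`r_e` well
below `f_e`·surplus/E).  With the values above, populations seeded at
10 nmol C on 500-chains show: endo growth only at M ∈ {150, 300, 500},
exo growth only at M ∈ {1000, 1500}, and growth at every tested M for
`fr_exo = 0.8`.  "Growth" means max(C_b) ≥ 2·C_b0.  Aliveness at the end
of a run is deliberately *not* part of the growth criterion: in a closed
microcosm every successful population exhausts its substrate and then
starves, so an alive-at-end clause would select for failure to grow.
Well-mixed runs default to 400 h with dt = 0.1 h, by which time the
boom–bust dynamics under these kinetics have resolved.

The death threshold 0.08 nmol C per microsite keeps the printed
magnitude of the source value whose unit (mol) is dimensionally
implausible at microsite scale.

## Spatial model

A `ny × nx` lattice (default 100×100, tests and examples use scaled
20–30² grids) of 10 µm microsites, each a well-mixed volume in the same
concentration units.  Per step (operator splitting): local reactions at
occupied sites → diffusion → division → random mortality.

* **Diffusion**: explicit 5-point Laplacian per soluble size class
  (i ≤ 10) with `D_i = D_0/i` (Rouse–Zimm, x = 1), `D_0 = 30 µm²/h`,
  no-flux boundaries (a closed microcosm, so the ledgers audit exactly).
  The step obeys `dt ≤ h²/(4 D_0)` (≈0.83 h at the defaults; configs
  violating it are rejected up front).  DIN does not diffuse by default
  (switchable).  Insoluble chains (i > 10) and enzymes never move;
  enzymes are wall-attached and travel only with dividing biomass.
* **Division**: a site above `division_threshold = 20 nmol C`
  (2·C_b0) moves half its biomass and half of each enzyme pool into a
  uniformly chosen empty von-Neumann neighbor (8-neighborhood by
  config); fully enclosed sites do not divide.  Sweep order is
  re-randomized every step.
* **Mortality**: each occupied site dies independently at
  `death_rate = 1e−4 h⁻¹`; the site's biomass and enzymes are removed
  and ledgered.
* **RNG**: one root seed spawns named substreams (placement, division,
  mortality), so toggling one stochastic process does not shift the
  draws of another; identical configs and seeds reproduce trajectories
  bit-for-bit.

The per-step reaction work is evaluated only on occupied sites and is
vectorized across them, so sparse colonies are cheap even with 500 size
classes per site.

## What the scenarios show — and known limitations

* Enzyme-only runs reproduce the two kinetic signatures: constant
  monomer release for exo (1.845 nmol/(mm³·h) for the reference pool)
  and a convex, concentration-delayed monomer curve for endo, with endo
  completing first on long chains and the gap closing on short ones.
* The fr_exo scan with a half-speed endo enzyme has an interior optimum
  at fr_exo ≈ 0.9 on a 0.05 grid (T_deg 232 h vs 236 h at 0.8 and
  312/409 h for the pure enzymes): synergy requires long chains and
  vanishes for short ones.
* On the lattice, the endo specialist loses most of its potential
  biomass to oligomer diffusion at `D_0 = 30` (single-site max-biomass
  ratio ≈ 0.16 vs ≈ 1.0 for exo at M = 150), and consortia of the two
  specialists coexist at M = 150 but collapse to exo dominance with endo
  extinction at M = 1500 (5/5 seeds each on the scaled 30×30 grid).

Limitations to keep in mind.  The synthetic initial states are idealized
monodisperse pools with spatially uniform substrate; real polysaccharide
pools are polydisperse, partially crystalline and sorbed to surfaces,
none of which is modeled (no adsorption, processivity or product
inhibition).  Dead biomass and decayed enzymes leave the system, so
long-horizon dynamics are boom–bust by construction; persistent
coexistence can only be transient.  Two consequences are documented
rather than patched: (1) at low substrate neither specialist can boom
spatially under parameters compatible with the well-mixed niche
structure, so endo colonies do not show expanding-annulus growth at
`D_0 = 30` — low-substrate consortium coexistence manifests as mutual
persistence, not joint expansion; and (2) with a half-speed endo enzyme
the low-substrate consortium still ends in mutual persistence (labeled
coexistence) because neither strategy can grow there, rather than in exo
takeover.  Within the endo specialist's survival range its maximum
biomass increases with M (more accessible carbon) before collapsing at
the niche edge; the confinement of the niches, not monotonicity of the
heights, is the robust structure.
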