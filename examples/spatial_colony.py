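"""Spatial lattice: colony expansion and diffusive loss of oligomers.

A scaled 20 x 20 lattice of 10-um microsites.  First a lone end-cleaver
colonist on a rich uniform pool grows and colonizes neighbors; then the
diffusive-loss experiment compares how much potential biomass each
specialist loses when soluble oligomers (sizes 1-10, D_i = 30/i um^2/h)
can drift away from a single non-dividing microsite.
"""
from depolysim import (
    Grid,
    KineticParams,
    MetabolicParams,
    diffusive_loss_experiment,
    run_spatial,
)
from depolysim.params import SpatialConfig

cfg = SpatialConfig(nx=20, ny=20, dt=0.2)
grid = Grid.initialize(cfg, KineticParams(), [MetabolicParams(fr_exo=1.0)],
                       M=1500.0, n=500, seed=0, colonists_per_taxon=1)
res = run_spatial(grid, t_end=300.0, record_every=50.0)
ts = res.timeseries
print("colony expansion (exo specialist, M = 1500):")
for _, row in ts.iterrows():
    print(f"  t = {row.time_h:5.0f} h: occupied sites = {int(row.sites_taxon0):3d}, "
          f"total biomass = {row.C_b_taxon0:8.1f} nmol C")

print("\ndiffusive loss at a single site (M = 150, D_0 = 30 um^2/h):")
for fr, kind in [(0.0, "endo"), (1.0, "exo ")]:
    r = diffusive_loss_experiment(fr_exo=fr, M=150.0, n=500, D_0=30.0,
                                  cfg=SpatialConfig(nx=15, ny=15, dt=0.2),
                                  t_end=400.0)
    print(f"  {kind}: max biomass ratio (with/without diffusion) = {r['ratio']:.2f}")
print("Random-scission producers leak soluble intermediates they cannot yet")
print("take up, losing most of their potential growth; end-cleavers convert")
print("chains to monomers on the spot and are barely affected.")
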