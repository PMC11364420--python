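"""Enzyme-only degradation: end-cleaving vs random-scission kinetics.

Degrades the same pool (300 nmol/mm^3 of monomer mass locked in chains
of 200 units) with 3 nmol C/mm^3 of either enzyme and compares the
monomer release dynamics and the total degradation time T_deg.
"""
import numpy as np

from depolysim import EnzymePool, KineticParams, init_pool, integrate_pbe

kin = KineticParams()          # k_exo = k_endo = 0.82, km = 0.5
pool = init_pool(M=300.0, n=200)
print(f"initial pool: N_200 = {pool.N[199]:.2f} nmol/mm^3, mass = {pool.total_mass:.0f}")

for label, enz in [("exo ", EnzymePool(E_exo=3.0)), ("endo", EnzymePool(E_endo=3.0))]:
    traj = integrate_pbe(pool.copy(), enz, kin, t_end=300.0, n_samples=300)
    early = traj.t <= 40.0
    slope = np.polyfit(traj.t[early], traj.monomers[early], 1)[0]
    print(f"{label}: T_deg = {traj.t_deg:7.1f} h | early release rate = "
          f"{slope:.3f} nmol/(mm^3 h) | monomers at 40 h = "
          f"{np.interp(40.0, traj.t, traj.monomers):6.1f}")

print("\nThe end-cleaver releases monomers at a constant rate set by the chain")
print("count; random scission starts slowly (cuts rarely produce monomers at")
print("first) but finishes the whole pool sooner on long chains.")
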