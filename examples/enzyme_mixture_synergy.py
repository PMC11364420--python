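"""Synergy of mixed enzyme pools: degradation time vs exo fraction.

A fixed 3 nmol C/mm^3 pool of the two enzymes, with the endo enzyme
turning over at half the exo rate, degrades 500 nmol/mm^3 held in
500-chains.  Mixing creates chain ends (endo) that the end-cleaver can
harvest, so an intermediate mixture beats both pure enzymes.
"""
import numpy as np

from depolysim import KineticParams, scan_frexo_degradation

kin = KineticParams(k_exo=0.82, k_endo=0.41)
res = scan_frexo_degradation(M=500.0, n=500, E_total=3.0, kin=kin,
                             frexo_grid=np.round(np.arange(0, 1.01, 0.1), 10))

print("fr_exo   T_deg [h]")
for _, row in res.timeseries.iterrows():
    print(f"  {row.fr_exo:4.2f}   {row.T_deg:8.1f}")
print(f"\nfastest mixture: fr_exo = {res.metrics['argmin_frexo']:.2f} "
      f"(T_deg = {res.metrics['min_T_deg']:.1f} h)")
print("Mostly-exo mixtures with a small endo admixture degrade the pool faster")
print("than either pure enzyme: the scission events multiply the chain ends")
print("that limit the (faster) end-cleaver.")
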