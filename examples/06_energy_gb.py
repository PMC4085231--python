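"""Evaluate AMBER-style energies, including the Generalized-Born term."""

import relmol as rm
from relmol import fixtures as fx

ff = fx.tiny_forcefield()
mol = fx.benzene()
rm.enumerate_terms(mol)          # angles, torsions, impropers from bonds

report = rm.energy_report(mol, ff, gb=True)
print(report)
print()
print("Coulomb constant in use:", rm.INVCHG2, "kcal*A/(mol*e^2)")
print("rederived from CODATA:  ", round(rm.derive_coulomb_constant(), 4))
# The GB term sums -INVCHG2 (1 - 1/78.5) q_i q_j / f_GB over distinct
# pairs with f_GB = sqrt(r^2 + a_i a_j exp(-r^2 / (2 a_i a_j))).
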