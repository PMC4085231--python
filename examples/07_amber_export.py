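"""Write AMBER prmtop + inpcrd files for a parameterised system."""

import io

import relmol as rm
from relmol import fixtures as fx

ff = fx.tiny_forcefield()
mol = fx.water()
rm.enumerate_terms(mol)

prm = io.StringIO()
rm.write_amber_prmtop(mol, ff, prm)
crd = io.StringIO()
rm.write_coordinates(mol, crd)

print(prm.getvalue()[:480])
print("...")
print(crd.getvalue())
# POINTERS reports NATOM=3, NRES=1; the CHARGE column is q * sqrt(332.05)
# so that q_i q_j / r read from the file is already kcal/mol.
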