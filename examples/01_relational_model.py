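"""Build a water molecule directly in the relational store.

The molecule owns atoms, bonds and the residue side by side; the residue
holds no atoms itself, only relations to them.  Property keys are hashed
base-40 integers behind the scenes.
"""

import relmol as rm

mol = rm.Molecule("wat")
res = mol.create(rm.RESD)
res.set_s("name", "WAT")

o = mol.create(rm.ATOM)
o.set_s("name", "O")
o.set_i("element", 8)
o.set_v("position", (0.0, 0.0, 0.0))
for k, pos in enumerate([(0.757, 0.586, 0.0), (-0.757, 0.586, 0.0)], start=1):
    h = mol.create(rm.ATOM)
    h.set_s("name", f"H{k}")
    h.set_i("element", 1)
    h.set_v("position", pos)
    bond = mol.create(rm.BOND)
    bond.relate(o)
    bond.relate(h)
    res.relate(h)
res.relate(o)

print(f"atoms={mol.natoms} bonds={mol.count(rm.BOND)} residues={mol.nresds}")
print("oxygen's bonds:", [b.user_id for b in o.related(rm.BOND)])
print("hash of 'position':", rm.encode_name("position"))
# atoms=3 bonds=2 residues=1 — counting is constant-time: the molecule owns
# the atom table directly, no residue traversal happens.
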