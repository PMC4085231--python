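"""Select atoms with the mask language: ids, ranges, names, distances."""

import relmol as rm
from relmol import fixtures as fx

chain = fx.peptide_chain(4)  # 12 atoms, 3 per residue

for expr in (":1-2", "@CA", "@4 < @5", ":1 | :4", "!(:1)"):
    ids = [a.user_id for a in rm.mask_atoms(chain, expr)]
    print(f"{expr:12s} -> {ids}")
# ':1-2' is residues 1-2 (atoms 1..6); '@4 < @5' is every atom within
# 5 Angstrom of atom 4, including atom 4 itself at distance zero.
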