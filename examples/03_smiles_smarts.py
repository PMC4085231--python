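"""Parse SMILES into the relational model and search it with SMARTS."""

import relmol as rm

acetate = rm.read_smiles("CC(=O)[O-]")
print("acetate:", acetate.natoms, "heavy atoms,",
      sum(a.get_i("nhyd") for a in acetate.atoms), "implicit hydrogens,",
      "net charge", sum(a.find_i("fcharge")[1] or 0 for a in acetate.atoms))

carbonyl = rm.read_smarts("[#6]=[#8]")
hits = rm.match_smarts(carbonyl, acetate)
print("C=O matches (0-based index pairs):", hits)
# One C=O match: atom 1 (the carboxyl carbon) to atom 2 (the carbonyl
# oxygen).  The charged oxygen is bonded singly, so it does not match.
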