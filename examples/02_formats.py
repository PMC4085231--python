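"""Round-trip a molecule through PDB, MOL2 and SDF text."""

import io

import relmol as rm
from relmol import fixtures as fx

mol = fx.benzene()
for fmt, writer, reader in [("pdb", rm.write_pdb, rm.read_pdb),
                            ("mol2", rm.write_mol2, rm.read_mol2),
                            ("sdf", rm.write_sdf, rm.read_sdf)]:
    buf = io.StringIO()
    writer(mol, buf)
    back = reader(buf.getvalue())
    print(f"{fmt}: {back.natoms} atoms, {back.count(rm.BOND)} bonds, "
          f"{back.nresds} residues")
# Each reader recovers the 12 atoms / 12 bonds of benzene; the formats
# differ only in which side-band fields (charges, types, b-factors) survive.
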