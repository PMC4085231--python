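# relmol

A foundational library for molecular modelling and computer-aided drug
design built on a **relational** molecule store: a molecule owns *all* of
its constituents — atoms, bonds, residues, angles, torsions, impropers —
directly, as typed columnar tables, with relations between them kept in
separate adjacency tables.  Nothing is nested: a residue does not "contain"
atoms, it merely relates to them.  This makes atom iteration and counting
constant-time, gives inter-residue bonds an unambiguous owner, and lets new
object kinds (say, a DNA strand) be added without touching existing code.

On top of the store, `relmol` provides the standard preparation pipeline a
simulation practitioner needs:

- **Formats** — PDB v3 (fixed-column), TRIPOS MOL2, MDL SDF V2000 readers
  and writers, plus a multi-molecule database loader.
- **Line notation** — a SMILES reader (organic subset, brackets with
  isotope/charge/H-count, rings, branches) and a SMARTS reader/matcher
  returning every subgraph monomorphism.
- **Structure repair** — bond-order perception (`fixbond`: hard
  functional-group templates, bond-length bands, Kekulization), hydrogen
  completion with idealised geometry, rigid-body transforms, geometric
  centres.
- **Selection** — an AMBER-style atom-mask language: `:1-10` (residues),
  `@4 < @5` (atoms within 5 Å of atom 4), names, ranges, `& | !`.
- **Solvation** — shell, cuboid box, truncated-octahedron box and cap
  builders over a tiled solvent template, with radius-scaled clash pruning,
  and counter-ion placement at Coulomb-potential extrema.
- **Energetics** — AMBER parameter-file parsing (frcmod dialect), term
  enumeration, bonded energies, direct nonbonded sums with 1-2/1-3
  exclusions and 1-4 scaling, and a pairwise **Generalized-Born** implicit
  solvent term (below).
- **AMBER export** — `%FLAG`-style prmtop and ASCII inpcrd files readable
  by current MD engines, plus a LEaP-like command interpreter and a thin
  `relmol` CLI.

## The Generalized-Born term

Polar desolvation for a non-periodic system is evaluated as

```
E_GB   = -INVCHG2 · (1 - 1/ε) · Σ_{i<j}  q_i q_j / f_GB(r_ij)
f_GB   = [ r_ij² + α_ij² · exp(-r_ij² / (2 α_ij²)) ]^½
α_ij²  = α_i α_j
```

with `ε = 78.5` (water), `INVCHG2 = 332.05 kcal·Å/(mol·e²)` and per-atom
effective Born radii `α_i` (an mbondi-like per-element table fills unset
values).  The sum runs over distinct pairs exactly as defined — no
self-energy term and no bonded exclusions.  At `r = 0`, `f_GB = α_ij`; at
`r ≫ α`, the pair term decays to screened Coulomb,
`-INVCHG2 (1 - 1/ε) q_i q_j / r`.

## Worked example

```python
import relmol as rm
from relmol import fixtures as fx

ff = fx.tiny_forcefield()          # packaged AMBER-dialect parameters
mol = fx.benzene()                 # 12 atoms, Kekulé orders, ideal geometry
rm.enumerate_terms(mol)            # angles/torsions/impropers from bonds
print(rm.energy_report(mol, ff, gb=True))
```

prints

```
bond              0.2814 kcal/mol
angle             0.0000 kcal/mol
torsion           0.0000 kcal/mol
improper          0.0000 kcal/mol
elec              1.8696 kcal/mol
vdw               3.7502 kcal/mol
egb              14.0245 kcal/mol
total            19.9257 kcal/mol
```

The 0.28 kcal/mol of bond strain is the six C–C bonds sitting at the
fixture's 1.39 Å against the force field's 1.40 Å equilibrium
(6 × 469 × 0.01² ≈ 0.28); angles and torsions are at their equilibria, and
the positive `egb` is the desolvation penalty of the alternating ring
charges at ε = 78.5.

More narrative walk-throughs live in `examples/` (one script per
capability: the relational store, formats, SMILES/SMARTS, masks, solvation
and ions, energies, AMBER export, command scripts).  The same pipeline is
scriptable from a shell:

```sh
relmol fixtures /tmp/fix
relmol energy --in /tmp/fix/benzene.mol2 --frc /tmp/fix/tiny.frcmod --gb
relmol run build.cmds              # LEaP-like command script
```

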