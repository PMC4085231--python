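# Methods

## The relational molecule store

A `Molecule` is a set of typed **component tables** plus **adjacency
tables**.  A component table holds one column per property, each a flat
array over that type's objects; numeric-vector properties (positions) are
flattened into a single 1-D array of width × count reals rather than an
array of vectors, trading indexing arithmetic for locality and space.  An
adjacency table is a per-source list of related target indices, stored in
both directions (atom→bond and bond→atom are separate tables), with
insertion order preserved — the order of a bond's two atoms defines its
(i, j) orientation, and the order of a term's atoms defines the angle or
dihedral evaluated from it.

Object handles are `(molecule, type, index)` triples carrying no data.
External numbering (file formats, the mask language) is 1-based; internal
indices are 0-based; conversion happens only at those boundaries.

Property and type names are keyed by a base-40 positional integer: letters
map to their position from `a`/`A` (both zero), digits to themselves,
underscore to 36, anything else is skipped, and the running sum is
multiplied by 40 per character.  Names are capped at 10 admissible
characters so the key fits a signed 64-bit integer (40¹⁰ < 2⁶³).  The code
is *not* injective across character classes — `a`, `A` and `0` all encode
to 0 — so distinct property names within one program should differ in more
than case or letter-versus-digit; the injectivity property holds (and is
tested) over lowercase letters and underscore.  Eight object types are
predefined (`atom bond resd angl tors oops tor2 ptor`); `tor2`/`ptor` exist
for extensibility and carry no energy model here.

**Deletion** compacts the columns, purges and re-indexes every adjacency
row, and cascades: removing an atom removes every bond, angle, torsion or
improper related to it, because those objects are meaningless without a
member.  This keeps referential integrity — every stored index is always a
valid row of its target table — which the suite fuzzes with random
create/relate/delete sequences.

## Formats

PDB parsing is fixed-column first with a whitespace fallback for slightly
nonconforming files; residues open on a change of `(resSeq, chain)`;
CONECT records become bonds and no bonds are otherwise inferred (perception
is `fixbond`'s job).  Element inference from blank element columns follows
the PDB naming convention (right-justified element, leading digits on
hydrogens, two-letter symbols only when the first name column is occupied).
MOL2 aromatic (`ar`) bonds are stored internally as order 4 and localized
only on demand; `am` (amide) is order 5 and treated as single for valence.
SDF is V2000 only; `M  CHG` lines supersede the legacy charge column; data
fields become molecule-level text properties.  Serial/id columns roll over
at their fixed widths.

## SMILES / SMARTS subset

SMILES: organic-subset atoms, bracket atoms with isotope, charge and
explicit H count, branches, ring labels 0–9 and `%nn`, bond symbols
`- = # :`, `.` for fragments; aromatic lowercase atoms must close into
rings (checked by leaf-stripping); stereo markers parse with a warning and
no semantics.  Implicit hydrogens are a per-atom count (`nhyd`), never atom
objects; the count is the smallest standard valence (B3 C4 N3,5 O2 P3,5
S2,4,6, halogens 1) minus the bond-order sum, with aromatic bonds at 1.5
and a charge adjustment (+q raises the target on lone-pair bearers, −q
lowers it).  The writer is non-canonical; round-trips are checked by graph
isomorphism, not string equality.

SMARTS: atomic number `#n`, element symbols (aromatic lowercase), `a`/`A`,
charge, degree `Dn`, ring membership `R`, wildcard `*`, with `!`, `&`/
juxtaposition, `,` and `;` at the conventional precedences (predicates
normalise to an OR-of-ANDs).  Anything else — recursive SMARTS, `H`/`X`/
`v` counts — raises an unsupported-token error rather than being silently
accepted.  Matching is exhaustive backtracking over subgraph monomorphisms,
deterministic and lexicographically ordered, with symmetric duplicates
retained (benzene's ring query yields 12 matches, cyclopropane's 6).  An
unwritten query bond means "single or aromatic".

## Atom masks

`:` selects residues, `@` atoms; items are 1-based ids, `n-m` ranges, or
names with an optional `*` suffix.  `expr < @r` keeps atoms whose minimum
distance to any core atom is ≤ r; the core atoms themselves qualify at
distance zero (a flag excludes them); `>` is the strict complement within
the molecule; `< :r` promotes the result to whole residues any of whose
atoms qualify.  `!` binds tighter than the postfix distance operator, so
`!(:3) < @5` needs its parentheses — the fuzz oracle renders negations
parenthesised for exactly this reason.  Whitespace is insignificant.

## Solvation

All four modes share one deterministic engine: stretch the solute bounding
box by the margin (shell `extent`, box/oct `buffer`, cap as needed), tile
solvent-template copies at spacing `solvlen` (the template cell edge) from
the stretched minimum corner including partial far cells, then prune each
candidate residue by

1. a **region test** on its centroid — box interior; the truncated
   octahedron keeps `|u|+|v|+|w| ≤ 3/2` in coordinates normalised by the
   half-lengths (for a cube this is the classic `|x|+|y|+|z| ≤ 3a/4` corner
   clipping, generalised so the octahedral count can never exceed the box
   count at equal buffer); or the cap sphere;
2. a **clash cut** — any solvent/solute atom pair closer than
   `closeness × (r1 + r2)` (Bondi van-der-Waals radii) discards the
   residue.  The additive variant `r1 + r2 + closeness` is selectable
   (`clash_rule="add"`); the multiplicative form is the default because
   `closeness` acts naturally as a dimensionless contact scale there;
3. for shells only, an **outer border** — minimum plain solute distance
   above `extent` discards.

Because shell and box prune from the same candidate grid, a shell is always
a subset of the equal-margin box.  The packaged 216-water cube template is
synthetic — a 3.104 Å jittered lattice with seeded random orientations
reproducing TIP3P density, standing in for an equilibrated box; no
relaxation is performed, so packing statistics near the solute are ideal-
lattice, not liquid-state.

`addions` places ions greedily at the extremum of a Coulomb potential
evaluated on a coarse grid (2 Å spacing, 6 Å margin), at least `closeness`
(default 3 Å) from every existing atom, updating the potential after each
placement; `auto` places ⌈|net charge|⌉ ions and requires the opposite
sign.

## Bond orders and hydrogens

`fixbond` applies three rules in order: **hard** functional-group templates
(carboxylate, nitro, guanidinium — an approximation of the fuller template
set the rule family comes from), a **length** rule from packaged per-order
covalent radii (order bands with ~0.05 Å slack; lengths falling between
the double and single bands are deferred), and a **conjugation** rule that
assigns alternating single/double orders over the deferred bonds by
deterministic lowest-index-first backtracking, requiring one double bond
per unsaturated atom (lone-pair bearers may take none).  Per-element
valence caps are asserted afterwards; an unassignable system raises with
the offending atoms.  `add_hydrogens` fills each heavy atom to its standard
valence at tabulated X–H lengths, choosing tetrahedral / trigonal / linear
directions from the steric number and aligning the ideal direction set to
existing substituents (Kabsch alignment; the last slot uses the exact
negated resultant).

## Energetics

Bonded terms are the AMBER forms `k(r−r0)²`, `k(θ−θ0)²` and
`(V/2)(1+cos(nφ−γ))`, with multi-term Fourier torsions and improper
dihedrals (trigonal C/N centres, centre third).  The parameter reader
handles the section-labelled (frcmod-style) dialect — MASS, BOND, ANGLE,
DIHE with negative-periodicity continuation lines, IMPROPER, NONBON — and
overlays replace matching keys.  Wildcard `X` matches any type with
most-specific-first resolution.

Direct nonbonded sums exclude 1-2/1-3 pairs and scale 1-4 pairs by 1/1.2
(electrostatics) and 1/2.0 (Lennard-Jones); a pair's class is its
*shortest* bond-graph separation, so ring pairs that are both 1-3 and 1-4
are excluded.  Under periodic boundary conditions the sum uses orthorhombic
minimum-image distances with a cutoff that must stay below half the
shortest box edge; no Ewald summation is implemented — truncated
minimum-image electrostatics is a deliberate simplification and PBC
energies should be read accordingly.  The Coulomb prefactor is
`INVCHG2 = 332.05 kcal·Å/(mol·e²)`; rederiving it from CODATA constants
gives 332.0637, the ~0.01 discrepancy being the historical rounding baked
into the AMBER convention (18.2223² = 332.0522); the package keeps 332.05
as its definition and exposes the derivation for comparison.

The GB term is evaluated exactly as defined in the README: distinct pairs,
no self-term, no exclusions, `f_GB = [r² + α_iα_j·exp(−r²/(2α_iα_j))]^½`.
The exponent denominator `2α_ij²` is the model's definition; the GB
literature more commonly uses `4α_iα_j` (i.e. twice as large), which is
available as `GBParameters(exponent_rule="literature")` — the two differ
measurably at intermediate separations and agree at r = 0 and r → ∞.  Born
radii are a per-atom input; absent values fall back to an mbondi-like
element table (H 1.2, C 1.7, N 1.55, O 1.5, S 1.8 … Å).

## AMBER topology export

The writer targets the modern `%FLAG` prmtop dialect (`10I8` / `5E16.8` /
`20a4` layouts) with the conventional sections through RADII/SCREEN/IPOL,
box metadata (SOLVENT_POINTERS, ATOMS_PER_MOLECULE, BOX_DIMENSIONS) when
the molecule carries box information, and a fixed version-stamp date so
output is reproducible byte-for-byte.  Charges are stored as
`q·√332.05 ≈ q·18.2222`, making `q_iq_j/r` read from the file directly
kcal/mol and keeping file-derived energies consistent with the internal
evaluator to well below the 1e-4 kcal/mol parity tolerance.  Dihedral
entries are coordinate-array offsets (3 × atom index); the third index is
negated to suppress duplicate 1-4 contributions (extra Fourier terms, ring
short-circuits), the fourth (and third) for impropers; where a sign would
land on atom 0 the quartet is stored reversed, which leaves the dihedral
angle — and hence the energy — unchanged.  Exclusion lists carry each
atom's 1-2/1-3/1-4 partners with `j > i`, with the mandatory single zero
for atoms having none.  Writing requires residue-contiguous atom ordering
(builders and readers produce it); H-containing versus H-free term
splitting keys on atomic number, not names.  Coordinates are the ASCII
restart layout: title, count, `%12.7f` six per line, box line when
periodic.

## Command layer and CLI

Script commands (`load`, `save`, `loadfrc`, `source`, `merge`, `translate`,
`solvate`, `addions`, `moloper`, `mask`, `energy`, `saveamberparm`,
`setpchg`, `parmchk`, `fixtures`, `quit`) share a uniform `exec()` contract
and one registry; `name = command args` binds results; the first failure
aborts with its line number.  `setpchg` is a stub applying a small
per-element electronegativity-equalisation (PEOE-style) charge model —
deterministic, charge-conserving, adequate for demonstrations, not a
substitute for AM1-BCC/RESP; `parmchk` reports missing parameters instead
of generating them.  The `relmol` CLI wraps the same library calls.

## Testing strategy and problem sizes

Every operation with a defined expected value is checked against an
independent oracle implemented in the test suite with plain loops: a
separate base-40 encoder, a naive mask interpreter over rendered random
ASTs (1,000 expressions, molecules up to 100 atoms), per-residue
brute-force solvent filters (50 random solutes), an O(n²) nonbonded
reference (systems of 50–200 atoms at ≥2 Å separations, so the 1e-9
kcal/mol comparison is not dominated by float summation order on clashed
LJ terms), an all-permutations SMARTS matcher (≤8-atom targets), and a
self-contained prmtop text parser + AMBER-form evaluator for topology
parity (1e-4 kcal/mol on water, methane, benzene, a peptide-like chain, a
water dimer and a solvated ion).  rdkit cross-checks SMILES semantics and
MDAnalysis independently re-reads written topologies.  Hypothesis runs
derandomised.  These sizes keep the full suite around a minute on one CPU
while leaving the brute-force oracles exhaustive at their scale; passing
them demonstrates internal consistency and agreement with the stated
definitions on synthetic inputs, not accuracy on experimental structures.

## Known limitations

- No Ewald summation, forces/gradients, or neighbour lists; energies only.
- AMOEBA object types are registered but carry no parameters or energy.
- The hard-rule template set is a small approximation; Kekulization
  assumes alternation is achievable with at most one double bond per atom.
- Hydrogen placement is idealised geometry, not rotamer-optimised, and
  ignores pKa.
- The synthetic water cube is unequilibrated; solvation counts are
  lattice-ideal.
- OFF-format databases and SDF V3000 are rejected explicitly.
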