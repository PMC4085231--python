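"""Build solvated systems: shell, box, truncated octahedron, counter-ions."""

import relmol as rm
from relmol import fixtures as fx

template = fx.single_water_template()

shell = fx.methane()
n_shell = rm.solvate_shell(shell, template, closeness=1.0, extent=6.0)

box = fx.methane()
n_box = rm.solvate_box(box, template, buffer=8.0)

oct_ = fx.methane()
n_oct = rm.solvate_oct(oct_, template, buffer=8.0)

print(f"shell: {n_shell} waters; box: {n_box}; oct: {n_oct} (oct <= box)")

charged = fx.peptide_chain()
for a in charged.atoms:
    if a.get_s("name") == "N":
        a.set_d("pchg", -0.8)  # net -2 over four residues
n_ions = rm.addions(charged, fx.sodium_ion(), "auto")
print(f"auto-neutralisation placed {n_ions} Na+ "
      f"(net charge now {sum(a.get_d('pchg') for a in charged.atoms):+.2f})")
# The octahedron clips the box corners, so it always needs at most as many
# waters; 'auto' places ceil(|net charge|) counter-ions at potential minima.
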