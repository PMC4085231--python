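"""Drive everything from a LEaP-like command script."""

import sys
import tempfile

from relmol import fixtures as fx
from relmol.script import run_script

d = tempfile.mkdtemp()
fx.generate_fixtures(d)

script = f"""
loadfrc {d}/tiny.frcmod
load {d}/methane.mol2
load {d}/water.mol2
translate wat 4.0 0 0
sys = merge mth wat
energy sys gb
saveamberparm sys {d}/sys.prmtop {d}/sys.inpcrd
quit
"""
status = run_script(script, out=sys.stdout)
print("exit status:", status)
# Each line is one registered command; the first failure aborts the script
# with its line number and a nonzero status.
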