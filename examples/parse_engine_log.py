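"""Extract shieldings and the SCF energy from an engine log.

The parser targets the common log dialect: "Magnetic shielding tensor
(ppm)" sections with "Isotropic =" atom lines and "SCF Done:" energy
lines (the last energy line wins). Any other engine can enter the
pipeline through the tidy interchange tables instead.
"""

import io

from shiftcal import parse_engine_log

LOG = """\
 SCF Done:  E(RB3LYP) =  -1403.05521433     A.U. after   13 cycles
 ... geometry steps ...
 SCF Done:  E(RB3LYP) =  -1403.05634871     A.U. after    9 cycles
 Magnetic shielding tensor (ppm):
      1  C    Isotropic =    65.7654   Anisotropy =    12.3456
      2  C    Isotropic =   187.9012   Anisotropy =    99.0000
      3  H    Isotropic =    25.1987   Anisotropy =     7.6543
"""

shieldings, energy_hartree = parse_engine_log(io.StringIO(LOG),
                                              conformer_id="conf001")
print(shieldings.to_string(index=False))
print(f"\nfinal SCF energy: {energy_hartree} hartree")

# Three atoms were extracted with their isotropic shieldings in ppm;
# the energy is the LAST SCF line (-1403.05634871), i.e. the converged
# single-point value, not an intermediate step.
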