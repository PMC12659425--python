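"""Physical constants and unit conversions.

Internal electrostatics is done in Hartree atomic units (Bohr, e, Hartree);
all file I/O and geometry input is in Angstrom.  The conversion constant is
defined here and nowhere else.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092
ANGSTROM_PER_BOHR = 0.52917721092

KCAL_PER_HARTREE = 627.509
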