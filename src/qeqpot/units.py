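"""Unit conversion constants (CODATA 2018).

Internal energetics are in Hartree atomic units (Ha, Ha/Bohr, e); geometry
is carried in Angstrom and converted to Bohr inside the electrostatics.
Files use Angstrom / eV / eV/A / e.
"""

#: Angstrom per Bohr
BOHR = 0.529177210903
#: eV per Hartree
HARTREE = 27.211386245988

ANGSTROM_TO_BOHR = 1.0 / BOHR
EV_TO_HARTREE = 1.0 / HARTREE
#: (eV/A) per (Ha/Bohr)
HA_BOHR_TO_EV_ANG = HARTREE / BOHR
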