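"""Physical constants and unit conversions.

All internal math is done in Hartree atomic units (length in Bohr, energy in
Hartree, time in a.u.).  File I/O converts at the boundary: structure files
carry Angstrom, spectra are reported in eV / nm.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988

#: one atomic unit of time in femtoseconds
FS_PER_AU_TIME = 2.418884326e-2

#: hc in eV*nm, for energy <-> wavelength conversion
EV_NM = 1239.84198
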