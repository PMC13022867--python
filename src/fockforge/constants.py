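"""Physical constants, unit conversions and per-element data.

All internal energies are in hartree and internal lengths in bohr; user-facing
geometry I/O is in angstrom. Conversion factors follow CODATA-2018.
"""

from __future__ import annotations

#: 1 hartree in kcal/mol, used for every human-facing error report.
HARTREE_TO_KCAL = 627.509474

#: Boltzmann constant in hartree/K; maps the annealing temperature (kelvin)
#: onto the energy scale of the loss function.
KB_HARTREE = 3.166811563e-6

#: 1 angstrom in bohr.
ANGSTROM_TO_BOHR = 1.8897261254578281
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

#: Electron mass per unified atomic mass unit (CODATA).
AMU_TO_ME = 1822.888486209

#: Hartree -> cm^-1 (for reporting vibrational frequencies).
HARTREE_TO_WAVENUMBER = 219474.6313632

ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

Z_ELEMENT = {z: el for el, z in ELEMENT_Z.items()}

#: Masses of the most abundant isotope (u); the conventional choice for
#: harmonic frequency analysis.
ELEMENT_MASS = {
    "H": 1.00782503207,
    "He": 4.002603254,
    "Li": 7.01600455,
    "Be": 9.0121822,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Ne": 19.9924401754,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Al": 26.98153863,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.972071,
    "Cl": 34.96885268,
    "Ar": 39.9623831225,
}

#: Covalent radii (angstrom, Cordero 2008); used only to bracket bond-length
#: scans, never in any energy expression.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
}
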