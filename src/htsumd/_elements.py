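"""Per-element parameter tables used across the package.

Masses are standard atomic weights (amu).  The Lennard-Jones and partial-charge
tables are deliberately small, published-style values: they parameterise the
built-in interaction-energy surrogate, not a validated force field, and can be
overridden per atom from the input files.
"""

from __future__ import annotations

MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
}

# 12-6 Lennard-Jones parameters per element: sigma (Angstrom), epsilon (kcal/mol)
LJ_SIGMA: dict[str, float] = {
    "H": 1.20,
    "C": 3.40,
    "N": 2.75,
    "O": 2.40,
    "F": 2.95,
    "P": 3.70,
    "S": 3.60,
}
LJ_EPSILON: dict[str, float] = {
    "H": 0.005,
    "C": 0.15,
    "N": 0.17,
    "O": 0.21,
    "F": 0.06,
    "P": 0.20,
    "S": 0.25,
}

DEFAULT_SIGMA = 3.30
DEFAULT_EPSILON = 0.10
DEFAULT_MASS = 12.011

# Default partial charges (e) when the input carries none.  Hydrogens bonded to
# a polar heavy atom get the polar-H value; all other hydrogens the apolar one.
PARTIAL_CHARGE: dict[str, float] = {
    "O": -0.40,
    "N": -0.35,
    "S": 0.00,
    "C": 0.00,
}
POLAR_H_CHARGE = 0.35
APOLAR_H_CHARGE = 0.05

APOLAR_ELEMENTS = frozenset({"C", "S"})
POLAR_ELEMENTS = frozenset({"N", "O"})


def mass_of(element: str) -> float:
    return MASSES.get(element.upper(), DEFAULT_MASS)


def lj_sigma(element: str) -> float:
    return LJ_SIGMA.get(element.upper(), DEFAULT_SIGMA)


def lj_epsilon(element: str) -> float:
    return LJ_EPSILON.get(element.upper(), DEFAULT_EPSILON)
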