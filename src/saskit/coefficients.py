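"""Editable coefficient tables for MW estimation and sequence statistics.

All empirical constants used by the molecular-weight estimators live
here, in one versioned place, with their provenance, and can be
overridden at run time (:func:`load_overrides` accepts a JSON file with
the same structure). Nothing downstream hard-codes them.
"""

from __future__ import annotations

import json
from copy import deepcopy
from pathlib import Path

__all__ = [
    "DEFAULT_COEFFICIENTS",
    "RESIDUE_MASSES",
    "RESIDUE_PSV",
    "WATER_MASS",
    "load_overrides",
]

# Volume-of-correlation MW calibration, per molecule class:
# MW = (QR / c) ** k with QR = Vc^2 / Rg in A^3.
# Constants from the volume-of-correlation MW calibration literature
# (protein: linear, c = 0.1231; RNA: c = 0.00934, k = 0.808).
#
# MoW-style estimate from the apparent Porod volume V' at truncated
# s_max: MW = V' * correction(s_max) / volume_per_dalton. The default
# correction is the identity polynomial (no truncation correction) and
# the default apparent-volume-to-mass divisor is 1.66 A^3/Da, the
# round-number rule of thumb for hydrated globular proteins; both are
# deliberately user-editable because published truncation-correction
# fits vary between implementations.
DEFAULT_COEFFICIENTS: dict = {
    "vc": {
        "protein": {"c": 0.1231, "k": 1.0},
        "nucleic": {"c": 0.00934, "k": 0.808},
    },
    "mow": {
        # correction polynomial in s_max (A^-1), low order first
        "correction": [1.0],
        "volume_per_dalton": 1.66,  # A^3 / Da
    },
    "psv_nucleic_default": 0.54,  # cm^3/g, single configurable default
}

# Average residue masses (Da), monomer mass minus one water; adding one
# water per chain gives the chain mass.
WATER_MASS = 18.0153
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

# Per-residue partial specific volumes (cm^3/g), consensus values of the
# classical amino-acid volume compilations; the sequence-level PSV is
# the mass-weighted mean.
RESIDUE_PSV: dict[str, float] = {
    "A": 0.74,
    "R": 0.70,
    "N": 0.62,
    "D": 0.60,
    "C": 0.63,
    "Q": 0.67,
    "E": 0.66,
    "G": 0.64,
    "H": 0.67,
    "I": 0.90,
    "L": 0.90,
    "K": 0.82,
    "M": 0.75,
    "F": 0.77,
    "P": 0.76,
    "S": 0.63,
    "T": 0.70,
    "W": 0.74,
    "Y": 0.71,
    "V": 0.86,
}


def load_overrides(path: str | Path | None) -> dict:
    """Return the coefficient tables, optionally merged with a JSON file.

    The JSON file may override any subset of the keys of
    ``DEFAULT_COEFFICIENTS`` (shallow merge per top-level section).
    """
    coeffs = deepcopy(DEFAULT_COEFFICIENTS)
    if path is None:
        return coeffs
    user = json.loads(Path(path).read_text())
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(coeffs.get(section), dict):
            coeffs[section].update(value)
        else:
            coeffs[section] = value
    return coeffs
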