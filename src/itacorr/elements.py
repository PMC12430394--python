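"""Element data: atomic numbers, covalent radii and Bragg–Slater radii.

Covalent radii are Cordero-type single-bond values; Bragg–Slater radii set the
element-dependent scale of the radial quadrature map. Both are stored in
Angstrom and exposed in bohr. The synthetic element "X" (used by the fixture
generators) borrows hydrogen's radii.
"""
from __future__ import annotations

from .constants import ANGSTROM_TO_BOHR
from .errors import ConfigurationError

# symbol: (Z, covalent radius / A, Bragg-Slater radius / A)
_TABLE: dict[str, tuple[int, float, float]] = {
    "H": (1, 0.31, 0.35),
    "He": (2, 0.28, 0.30),
    "Li": (3, 1.28, 1.45),
    "Be": (4, 0.96, 1.05),
    "B": (5, 0.84, 0.85),
    "C": (6, 0.76, 0.70),
    "N": (7, 0.71, 0.65),
    "O": (8, 0.66, 0.60),
    "F": (9, 0.57, 0.50),
    "Ne": (10, 0.58, 0.45),
    "Na": (11, 1.66, 1.80),
    "Mg": (12, 1.41, 1.50),
    "Al": (13, 1.21, 1.25),
    "Si": (14, 1.11, 1.10),
    "P": (15, 1.07, 1.00),
    "S": (16, 1.05, 1.00),
    "Cl": (17, 1.02, 1.00),
    "Ar": (18, 1.06, 0.95),
    "X": (1, 0.31, 0.35),
}

#: bond detection: atoms closer than BOND_FACTOR * (sum of covalent radii) bond
BOND_FACTOR = 1.2


def atomic_number(symbol: str) -> int:
    try:
        return _TABLE[symbol][0]
    except KeyError:
        raise ConfigurationError(f"unknown element symbol: {symbol!r}") from None


def covalent_radius_bohr(symbol: str) -> float:
    try:
        return _TABLE[symbol][1] * ANGSTROM_TO_BOHR
    except KeyError:
        raise ConfigurationError(f"unknown element symbol: {symbol!r}") from None


def bragg_radius_bohr(symbol: str) -> float:
    try:
        return _TABLE[symbol][2] * ANGSTROM_TO_BOHR
    except KeyError:
        raise ConfigurationError(f"unknown element symbol: {symbol!r}") from None


def known_elements() -> tuple[str, ...]:
    return tuple(_TABLE)
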