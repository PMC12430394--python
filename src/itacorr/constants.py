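"""Physical constants and unit conversions (Hartree atomic units internally)."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

#: 1 Angstrom in bohr (CODATA)
ANGSTROM_TO_BOHR = 1.8897261254578281
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

#: 1 millihartree in hartree
MILLIHARTREE = 1.0e-3

#: densities below this value are excluded from logarithmic integrands
DENSITY_FLOOR = 1.0e-12


def _ck() -> float:
    return 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)


@dataclass(frozen=True)
class GBPConstants:
    """Constants of the Ghosh–Berkowitz–Parr entropy functional.

    k is the Boltzmann constant, equal to 1 in atomic units; c_K is the
    Thomas–Fermi constant entering t_TF = c_K rho^(5/3); c = 5/3 + ln(4 pi c_K / 3).
    """

    k: float = 1.0
    c_k: float = field(default_factory=_ck)

    @property
    def c(self) -> float:
        return 5.0 / 3.0 + math.log(4.0 * math.pi * self.c_k / 3.0)


GBP = GBPConstants()
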