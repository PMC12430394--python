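"""Shared fixtures and independent numerical oracles."""
from __future__ import annotations

import numpy as np
import pytest

from itacorr.density import AtomReference, GaussianExpansionField
from itacorr.geometry import Geometry
from itacorr.grids import build_grid


def radial_oracle(f, rmax: float = 15.0, n: int = 10_000) -> float:
    """Independent 1-D quadrature of a spherically symmetric integrand:
    4 pi int f(r) r^2 dr on a dense trapezoid grid."""
    r = np.linspace(1e-8, rmax, n)
    return float(np.trapezoid(4.0 * np.pi * r**2 * f(r), r))


def unit_gaussian_field(alpha: float, n_elec: float = 1.0) -> GaussianExpansionField:
    """Normalized single-center Gaussian density: N (alpha/pi)^(3/2) e^(-alpha r^2)."""
    return GaussianExpansionField(np.zeros((1, 3)), [n_elec], [alpha])


@pytest.fixture(scope="session")
def one_center_geom() -> Geometry:
    return Geometry(("X",), np.zeros((1, 3)))


@pytest.fixture(scope="session")
def one_center_grid(one_center_geom):
    return build_grid(one_center_geom)


@pytest.fixture(scope="session")
def synth_refs() -> dict[str, AtomReference]:
    return {"X": AtomReference("X", (1.0,), (1.0,))}
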