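"""Orbital-backed density fields from single-determinant wavefunctions.

Supports contracted Gaussian basis sets with real spherical-harmonic shells
(s, p, d). Basis functions are expanded into Cartesian monomials times a
Gaussian radial factor, so values, gradients and Laplacians are analytic.

Molden conventions: contraction coefficients refer to unit-normalized
primitives; spherical component order is s; (px, py, pz); (d0, d+1, d-1,
d+2, d-2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .density import DensityField
from .errors import ContractError, UnsupportedFormatError
from .geometry import Geometry

__all__ = ["BasisShell", "WavefunctionRecord", "OrbitalSet", "wavefunction_field"]

_SQRT3 = math.sqrt(3.0)

#: (l, m-slot) -> list of (coefficient, (i, j, k)) Cartesian monomial terms
_SOLID_HARMONICS: dict[int, list[list[tuple[float, tuple[int, int, int]]]]] = {
    0: [[(1.0, (0, 0, 0))]],
    1: [
        [(1.0, (1, 0, 0))],  # px
        [(1.0, (0, 1, 0))],  # py
        [(1.0, (0, 0, 1))],  # pz
    ],
    2: [
        [(-0.5, (2, 0, 0)), (-0.5, (0, 2, 0)), (1.0, (0, 0, 2))],  # d0
        [(_SQRT3, (1, 0, 1))],  # d+1
        [(_SQRT3, (0, 1, 1))],  # d-1
        [(_SQRT3 / 2.0, (2, 0, 0)), (-_SQRT3 / 2.0, (0, 2, 0))],  # d+2
        [(_SQRT3, (1, 1, 0))],  # d-2
    ],
}

_ANGULAR_LETTER = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}


def primitive_norm(l: int, alpha: float) -> float:
    """Normalization of a spherical-harmonic Gaussian primitive of exponent alpha."""
    base = (2.0 * alpha / math.pi) ** 0.75
    if l == 0:
        return base
    if l == 1:
        return base * 2.0 * math.sqrt(alpha)
    if l == 2:
        return base * 4.0 * alpha / _SQRT3
    raise UnsupportedFormatError(f"angular momentum l={l} not supported (s, p, d only)")


@dataclass(frozen=True)
class BasisShell:
    """One contracted shell: atom index, angular momentum, primitives."""

    atom: int
    l: int
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]  # for unit-normalized primitives

    def __post_init__(self) -> None:
        if len(self.exponents) != len(self.coefficients) or not self.exponents:
            raise ContractError("shell exponents/coefficients mismatch")
        if self.l not in (0, 1, 2):
            raise UnsupportedFormatError(
                f"angular momentum l={self.l} not supported (s, p, d only)"
            )

    @property
    def nfuncs(self) -> int:
        return 2 * self.l + 1


@dataclass(frozen=True)
class WavefunctionRecord:
    """Basis shells + MO coefficients + occupations for one determinant."""

    shells: tuple[BasisShell, ...]
    mo_coefficients: np.ndarray  # (nbasis, nmo)
    occupations: np.ndarray  # (nmo,)
    spherical: bool = True
    energies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.spherical:
            raise UnsupportedFormatError(
                "Cartesian d/f shells are not supported; spherical-harmonic sets only"
            )
        c = np.asarray(self.mo_coefficients, dtype=float)
        occ = np.asarray(self.occupations, dtype=float)
        nbasis = sum(sh.nfuncs for sh in self.shells)
        if c.ndim != 2 or c.shape[0] != nbasis:
            raise ContractError(
                f"MO coefficient matrix has {c.shape} rows; basis dimension is {nbasis}"
            )
        if c.shape[1] != len(occ):
            raise ContractError("occupations length does not match number of MOs")
        if np.any(occ < 0):
            raise ContractError("occupations must be non-negative")
        object.__setattr__(self, "mo_coefficients", c)
        object.__setattr__(self, "occupations", occ)

    @property
    def nbasis(self) -> int:
        return sum(sh.nfuncs for sh in self.shells)


def _eval_basis(
    record: WavefunctionRecord, geom: Geometry, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Basis values (n, nb), gradients (n, nb, 3) and Laplacians (n, nb)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    nb = record.nbasis
    val = np.zeros((n, nb))
    grad = np.zeros((n, nb, 3))
    lap = np.zeros((n, nb))

    col = 0
    for sh in record.shells:
        d = pts - geom.coords[sh.atom]
        r2 = np.einsum("ni,ni->n", d, d)
        x, y, z = d[:, 0], d[:, 1], d[:, 2]
        for m, terms in enumerate(_SOLID_HARMONICS[sh.l]):
            for cprim, alpha in zip(sh.coefficients, sh.exponents):
                pref = cprim * primitive_norm(sh.l, alpha)
                e = pref * np.exp(-alpha * r2)
                for coef, (i, j, k) in terms:
                    mono = x**i * y**j * z**k
                    val[:, col + m] += coef * mono * e
                    # d/dx [x^i e] = (i x^(i-1) - 2 a x^(i+1)) e, etc.
                    gx = (i * x ** (i - 1) if i else 0.0) - 2.0 * alpha * x ** (i + 1)
                    gy = (j * y ** (j - 1) if j else 0.0) - 2.0 * alpha * y ** (j + 1)
                    gz = (k * z ** (k - 1) if k else 0.0) - 2.0 * alpha * z ** (k + 1)
                    grad[:, col + m, 0] += coef * gx * y**j * z**k * e
                    grad[:, col + m, 1] += coef * x**i * gy * z**k * e
                    grad[:, col + m, 2] += coef * x**i * y**j * gz * e
                    ll = i + j + k
                    lap_poly = (
                        -2.0 * alpha * (2 * ll + 3) * mono + 4.0 * alpha**2 * mono * r2
                    )
                    if i >= 2:
                        lap_poly += i * (i - 1) * x ** (i - 2) * y**j * z**k
                    if j >= 2:
                        lap_poly += j * (j - 1) * x**i * y ** (j - 2) * z**k
                    if k >= 2:
                        lap_poly += k * (k - 1) * x**i * y**j * z ** (k - 2)
                    lap[:, col + m] += coef * lap_poly * e
        col += sh.nfuncs
    return val, grad, lap


@dataclass
class OrbitalSet:
    """Occupied-orbital values and derivatives at a fixed point set."""

    occupations: np.ndarray  # (nocc,)
    values: np.ndarray  # (n, nocc)
    gradients: np.ndarray  # (n, nocc, 3)
    laplacians: np.ndarray  # (n, nocc)

    def orbital_densities(self) -> np.ndarray:
        """rho_i = occ_i |phi_i|^2, shape (n, nocc)."""
        return self.occupations[None, :] * self.values**2


class WavefunctionField(DensityField):
    """Density field rho = sum_i occ_i |phi_i|^2 built from a WavefunctionRecord."""

    has_orbitals = True

    def __init__(self, record: WavefunctionRecord, geom: Geometry):
        occupied = np.nonzero(record.occupations > 0)[0]
        if len(occupied) == 0:
            raise ContractError("all occupations are zero: empty density")
        self.record = record
        self.geom = geom
        self._occ_idx = occupied
        self.occupations = record.occupations[occupied]
        self.n_electrons = float(self.occupations.sum())
        self._cache_pts: np.ndarray | None = None
        self._cache: OrbitalSet | None = None

    def orbitals(self, points: np.ndarray) -> OrbitalSet:
        """Occupied orbitals evaluated at ``points`` (cached for reuse)."""
        if self._cache_pts is points and self._cache is not None:
            return self._cache
        bval, bgrad, blap = _eval_basis(self.record, self.geom, points)
        c = self.record.mo_coefficients[:, self._occ_idx]
        orbs = OrbitalSet(
            occupations=self.occupations,
            values=bval @ c,
            gradients=np.einsum("nbi,bo->noi", bgrad, c),
            laplacians=blap @ c,
        )
        self._cache_pts = points
        self._cache = orbs
        return orbs

    def rho(self, points: np.ndarray) -> np.ndarray:
        o = self.orbitals(points)
        return o.orbital_densities().sum(axis=1)

    def grad_rho(self, points: np.ndarray) -> np.ndarray:
        o = self.orbitals(points)
        return 2.0 * np.einsum("o,no,noi->ni", o.occupations, o.values, o.gradients)

    def lap_rho(self, points: np.ndarray) -> np.ndarray:
        o = self.orbitals(points)
        grad2 = np.einsum("noi,noi->no", o.gradients, o.gradients)
        return 2.0 * (o.occupations * (o.values * o.laplacians + grad2)).sum(axis=1)

    def kinetic_density(self, points: np.ndarray) -> np.ndarray:
        """Noninteracting kinetic-energy density from canonical orbital densities.

        t = sum_i (1/8) |grad rho_i|^2 / rho_i - (1/8) lap rho, which for
        rho_i = occ_i |phi_i|^2 reduces to sum_i occ_i |grad phi_i|^2 / 2
        - (1/8) lap rho; it integrates to the total kinetic energy T_S.
        """
        o = self.orbitals(points)
        grad2 = np.einsum("noi,noi->no", o.gradients, o.gradients)
        positive = 0.5 * (o.occupations * grad2).sum(axis=1)
        return positive - 0.125 * self.lap_rho(points)


def wavefunction_field(record: WavefunctionRecord, geom: Geometry) -> WavefunctionField:
    """Build the orbital-backed density field for a wavefunction record."""
    if len(record.shells) and max(sh.atom for sh in record.shells) >= geom.natoms:
        raise ContractError("shell atom index out of range for geometry")
    return WavefunctionField(record, geom)
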