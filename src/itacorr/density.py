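"""Electron-density fields.

A :class:`DensityField` yields the total density rho, its gradient and its
Laplacian at arbitrary points (bohr). The promolecular field is a superposition
of packaged per-element s-Gaussian expansions of spherically averaged
neutral-atom densities; all of its derivatives are analytic.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ContractError
from .geometry import Geometry

__all__ = [
    "AtomReference",
    "DensityField",
    "GaussianExpansionField",
    "load_atom_references",
    "promolecular_field",
]


@dataclass(frozen=True)
class AtomReference:
    """Reference (free-atom) density as an s-Gaussian expansion.

    rho0(r) = sum_k c_k (alpha_k/pi)^(3/2) exp(-alpha_k r^2), with the c_k in
    electrons (summing to n_elec) and alpha_k in bohr^-2.
    """

    element: str
    coeffs: tuple[float, ...]
    exponents: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coeffs) != len(self.exponents) or not self.coeffs:
            raise ContractError("coeffs/exponents must be equal-length and non-empty")
        if any(a <= 0 for a in self.exponents):
            raise ContractError("exponents must be positive")

    @property
    def n_elec(self) -> float:
        return float(sum(self.coeffs))

    def rho(self, r: np.ndarray) -> np.ndarray:
        """Spherically symmetric density at radial distances r (bohr)."""
        r2 = np.asarray(r, dtype=float) ** 2
        out = np.zeros_like(r2)
        for c, a in zip(self.coeffs, self.exponents):
            out += c * (a / math.pi) ** 1.5 * np.exp(-a * r2)
        return out


class DensityField:
    """Contract for electron-density evaluation.

    Subclasses provide ``rho``, ``grad_rho`` and ``lap_rho`` over (n, 3) point
    arrays in bohr, plus the total electron count ``n_electrons``. Fields that
    expose canonical orbital densities set ``has_orbitals`` and implement
    ``kinetic_density``.
    """

    n_electrons: float
    has_orbitals: bool = False

    def rho(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def grad_rho(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def lap_rho(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def kinetic_density(self, points: np.ndarray) -> np.ndarray:
        from .errors import CapabilityError

        raise CapabilityError("this density field does not expose orbital densities")


class GaussianExpansionField(DensityField):
    """Sum of s-Gaussians on fixed centers: rho = sum_k c_k (a_k/pi)^(3/2) e^{-a_k |r-R_k|^2}.

    Covers promolecular densities, isolated reference atoms and the synthetic
    Gaussian-atom fixtures. Gradient and Laplacian are analytic:
    grad g = -2 a (r - R) g and lap g = (4 a^2 |r-R|^2 - 6 a) g.
    """

    def __init__(self, centers: np.ndarray, coeffs: np.ndarray, exponents: np.ndarray):
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        coeffs = np.asarray(coeffs, dtype=float)
        exponents = np.asarray(exponents, dtype=float)
        if centers.shape[1] != 3:
            raise ContractError("centers must be (m, 3)")
        if not (len(centers) == len(coeffs) == len(exponents)):
            raise ContractError("centers/coeffs/exponents must have equal length")
        self.centers = centers
        self.coeffs = coeffs
        self.exponents = exponents
        self.n_electrons = float(coeffs.sum())

    def _shell_values(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-shell Gaussian values g_k(points) and displacement vectors."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        disp = pts[:, None, :] - self.centers[None, :, :]  # (n, m, 3)
        r2 = np.einsum("nmi,nmi->nm", disp, disp)
        g = self.coeffs * (self.exponents / math.pi) ** 1.5 * np.exp(-self.exponents * r2)
        return g, disp

    def rho(self, points: np.ndarray) -> np.ndarray:
        g, _ = self._shell_values(points)
        return g.sum(axis=1)

    def grad_rho(self, points: np.ndarray) -> np.ndarray:
        g, disp = self._shell_values(points)
        return np.einsum("nm,nmi->ni", -2.0 * self.exponents * g, disp)

    def lap_rho(self, points: np.ndarray) -> np.ndarray:
        g, disp = self._shell_values(points)
        r2 = np.einsum("nmi,nmi->nm", disp, disp)
        return ((4.0 * self.exponents**2 * r2 - 6.0 * self.exponents) * g).sum(axis=1)

    def __add__(self, other: "GaussianExpansionField") -> "GaussianExpansionField":
        return GaussianExpansionField(
            np.vstack([self.centers, other.centers]),
            np.concatenate([self.coeffs, other.coeffs]),
            np.concatenate([self.exponents, other.exponents]),
        )


def load_atom_references(path: str | Path | None = None) -> dict[str, AtomReference]:
    """Load the packaged (or a user-supplied) promolecular atom table."""
    if path is None:
        source = resources.files("itacorr.data").joinpath("atoms.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    shells: dict[str, list[tuple[float, float]]] = {}
    for rec in csv.DictReader(rows):
        shells.setdefault(rec["element"], []).append((float(rec["c"]), float(rec["alpha"])))
    refs = {}
    for el, pairs in shells.items():
        cs, als = zip(*pairs)
        # renormalize to the integer electron count (CSV rounding leaves ~1e-11)
        n = round(sum(cs))
        scale = n / sum(cs)
        refs[el] = AtomReference(el, tuple(c * scale for c in cs), als)
    return refs


def atom_field(ref: AtomReference, center: np.ndarray) -> GaussianExpansionField:
    """Isolated-atom density field for one reference atom at ``center`` (bohr)."""
    m = len(ref.coeffs)
    centers = np.tile(np.asarray(center, dtype=float), (m, 1))
    return GaussianExpansionField(centers, np.array(ref.coeffs), np.array(ref.exponents))


def promolecular_field(
    geom: Geometry, refs: dict[str, AtomReference] | None = None
) -> GaussianExpansionField:
    """Superposition of neutral free-atom densities at the molecular geometry.

    The promolecule is always the neutral-atom superposition; the molecular
    charge does not enter. Raises a configuration error naming any element
    missing from ``refs``.
    """
    if refs is None:
        refs = load_atom_references()
    missing = sorted({el for el in geom.elements if el not in refs})
    if missing:
        raise ConfigurationError(
            "no promolecular reference density for element(s): " + ", ".join(missing)
        )
    centers, coeffs, exps = [], [], []
    for el, xyz in zip(geom.elements, geom.coords):
        ref = refs[el]
        for c, a in zip(ref.coeffs, ref.exponents):
            centers.append(xyz)
            coeffs.append(c)
            exps.append(a)
    field = GaussianExpansionField(np.array(centers), np.array(coeffs), np.array(exps))
    return field
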