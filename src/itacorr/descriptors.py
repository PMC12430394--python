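"""Information-theoretic density descriptors and the Hirshfeld partition.

The eleven descriptors, all in atomic units:

* Shannon entropy            S_S   = -int rho ln rho
* Fisher information         I_F   = int |grad rho|^2 / rho
* Ghosh-Berkowitz-Parr       S_GBP = int (3/2) k rho [c + ln(t/t_TF)]
* Onicescu information       E_n   = 1/(n-1) int rho^n        (n = 2, 3)
* relative Renyi (integral)  Omega_n = int rho^n / (rho0)^(n-1); this is the
  quantity tabulated as R2r/R3r; the literal entropy form
  1/(1-n) log10 Omega_n is also provided
* information gain           I_G   = int rho ln(rho/rho0)
* relative Fisher G1, G2, G3 summed over Hirshfeld atoms against free-atom
  references.

S_GBP uses the positive overall sign (the Ghosh-Berkowitz-Parr convention);
G1 uses the logarithmic integrand int lap(rho_A) ln(rho_A/rho0_A).

Points where the density falls below DENSITY_FLOOR are excluded from
logarithmic integrands; their contribution is below grid accuracy.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .constants import DENSITY_FLOOR, GBP, GBPConstants
from .density import AtomReference, DensityField, atom_field, load_atom_references
from .errors import CapabilityError, ContractError, DomainError
from .geometry import Geometry
from .grids import Quadrature, integrate

logger = logging.getLogger(__name__)

__all__ = [
    "ITAVector",
    "HirshfeldPartition",
    "shannon_entropy",
    "fisher_information",
    "gbp_entropy",
    "onicescu",
    "relative_renyi_integral",
    "relative_renyi_entropy",
    "information_gain",
    "hirshfeld",
    "relative_fisher_g",
    "compute_all",
]


@dataclass(frozen=True)
class ITAVector:
    """The eleven descriptor values (atomic units); S_GBP is None for fields
    without orbital densities."""

    SS: float
    IF: float
    SGBP: float | None
    E2: float
    E3: float
    R2r: float
    R3r: float
    IG: float
    G1: float
    G2: float
    G3: float

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def shannon_entropy(field: DensityField, grid: Quadrature) -> float:
    """-int rho ln rho (global delocalization of the density)."""
    rho = field.rho(grid.points)
    mask = rho > DENSITY_FLOOR
    vals = np.zeros_like(rho)
    vals[mask] = -rho[mask] * np.log(rho[mask])
    return integrate(grid, vals)


def fisher_information(field: DensityField, grid: Quadrature) -> float:
    """int |grad rho|^2 / rho (local sharpness of the density)."""
    rho = field.rho(grid.points)
    grad = field.grad_rho(grid.points)
    mask = rho > DENSITY_FLOOR
    vals = np.zeros_like(rho)
    g2 = np.einsum("ni,ni->n", grad, grad)
    vals[mask] = g2[mask] / rho[mask]
    return integrate(grid, vals)


def gbp_entropy(
    field: DensityField, grid: Quadrature, constants: GBPConstants = GBP
) -> float:
    """Ghosh-Berkowitz-Parr entropy int (3/2) k rho [c + ln(t/t_TF)].

    Requires orbital densities for the noninteracting kinetic-energy density t.
    Points with t <= 0 (numerically possible near nuclei and tails) or with
    rho below the floor are skipped; the skipped count is logged.
    """
    if not field.has_orbitals:
        raise CapabilityError("S_GBP requires an orbital-backed density field")
    rho = field.rho(grid.points)
    t = field.kinetic_density(grid.points)
    t_tf = constants.c_k * np.maximum(rho, 0.0) ** (5.0 / 3.0)
    mask = (rho > DENSITY_FLOOR) & (t > 0.0)
    skipped = int(np.count_nonzero((rho > DENSITY_FLOOR) & ~(t > 0.0)))
    if skipped:
        logger.info("gbp_entropy: skipped %d points with t(r) <= 0", skipped)
    vals = np.zeros_like(rho)
    vals[mask] = (
        1.5 * constants.k * rho[mask] * (constants.c + np.log(t[mask] / t_tf[mask]))
    )
    return integrate(grid, vals)


def onicescu(field: DensityField, grid: Quadrature, n: int) -> float:
    """Onicescu information energy E_n = 1/(n-1) int rho^n."""
    if n < 2:
        raise DomainError(f"Onicescu order must be >= 2; got {n}")
    rho = field.rho(grid.points)
    return integrate(grid, rho**n) / (n - 1)


def relative_renyi_integral(
    field: DensityField, ref_field: DensityField, grid: Quadrature, n: int
) -> float:
    """Omega_n = int rho^n / (rho0)^(n-1) — the tabulated R2r/R3r quantity."""
    if n < 2:
        raise DomainError(f"Renyi order must be >= 2; got {n}")
    rho = field.rho(grid.points)
    rho0 = np.maximum(ref_field.rho(grid.points), DENSITY_FLOOR)
    return integrate(grid, rho**n / rho0 ** (n - 1))


def relative_renyi_entropy(
    field: DensityField, ref_field: DensityField, grid: Quadrature, n: int
) -> float:
    """Literal relative Renyi entropy 1/(1-n) log10 Omega_n."""
    omega = relative_renyi_integral(field, ref_field, grid, n)
    if omega <= 0:
        raise DomainError(f"Renyi integral Omega_{n} = {omega} is not positive")
    return math.log10(omega) / (1 - n)


def information_gain(
    field: DensityField, ref_field: DensityField, grid: Quadrature
) -> float:
    """Kullback-Leibler divergence int rho ln(rho/rho0) of rho from rho0."""
    rho = field.rho(grid.points)
    rho0 = ref_field.rho(grid.points)
    mask = (rho > DENSITY_FLOOR) & (rho0 > DENSITY_FLOOR)
    vals = np.zeros_like(rho)
    vals[mask] = rho[mask] * np.log(rho[mask] / rho0[mask])
    return integrate(grid, vals)


class HirshfeldPartition:
    """Hirshfeld stockholder partition on a fixed grid.

    omega_A(r) = rho0_A(r) / sum_B rho0_B(r); rho_A = omega_A rho. Stores the
    per-atom free-atom densities and the derivatives needed by the relative
    Fisher descriptors.
    """

    def __init__(
        self,
        geom: Geometry,
        refs: dict[str, AtomReference],
        field: DensityField,
        grid: Quadrature,
    ):
        self.geom = geom
        self.field = field
        self.grid = grid
        natom, npts = geom.natoms, grid.npts
        self.rho0_atom = np.empty((natom, npts))
        self.lap0_atom = np.empty((natom, npts))
        grad0 = np.zeros((npts, 3))
        for a, (el, xyz) in enumerate(zip(geom.elements, geom.coords)):
            if el not in refs:
                from .errors import ConfigurationError

                raise ConfigurationError(f"no reference density for element {el!r}")
            af = atom_field(refs[el], xyz)
            self.rho0_atom[a] = af.rho(grid.points)
            self.lap0_atom[a] = af.lap_rho(grid.points)
            grad0 += af.grad_rho(grid.points)
        self.rho0_promol = self.rho0_atom.sum(axis=0)
        self.grad0_promol = grad0
        # omega_A = rho0_A / rho0_promol; where the promolecule underflows the
        # floor (far tails, zero weight in any integral) share uniformly so the
        # partition of unity holds pointwise
        self.weights = np.full((natom, npts), 1.0 / natom)
        ok = self.rho0_promol > DENSITY_FLOOR
        self.weights[:, ok] = self.rho0_atom[:, ok] / self.rho0_promol[ok][None, :]

    @property
    def natoms(self) -> int:
        return len(self.rho0_atom)

    def atomic_density(self, a: int) -> np.ndarray:
        """rho_A = omega_A rho at the grid points."""
        return self.weights[a] * self.field.rho(self.grid.points)

    def atomic_populations(self) -> np.ndarray:
        rho = self.field.rho(self.grid.points)
        return np.array(
            [integrate(self.grid, self.weights[a] * rho) for a in range(self.natoms)]
        )


def hirshfeld(
    geom: Geometry,
    refs: dict[str, AtomReference],
    field: DensityField,
    grid: Quadrature,
) -> HirshfeldPartition:
    """Build the Hirshfeld stockholder partition of ``field`` on ``grid``."""
    return HirshfeldPartition(geom, refs, field, grid)


def relative_fisher_g(
    partition: HirshfeldPartition,
    field: DensityField,
    grid: Quadrature,
    which: int,
) -> float:
    """Relative Fisher descriptors G1, G2, G3 summed over Hirshfeld atoms.

    Because the Hirshfeld ratio rho_A/rho0_A equals rho/rho0 (promolecule) at
    every point and sum_A rho_A = rho, the atomic sums collapse to:

    G1 = int lap(rho) ln(rho/rho0)
    G2 = int lap(rho) - sum_A int omega_A rho lap(rho0_A)/rho0_A
    G3 = int rho |grad ln(rho/rho0)|^2
    """
    if which not in (1, 2, 3):
        raise DomainError(f"which must be 1, 2 or 3; got {which}")
    if partition.grid is not grid:
        raise ContractError("partition was built on a different grid")
    rho = field.rho(grid.points)
    rho0 = partition.rho0_promol
    mask = (rho > DENSITY_FLOOR) & (rho0 > DENSITY_FLOOR)
    vals = np.zeros_like(rho)
    if which == 1:
        lap = field.lap_rho(grid.points)
        vals[mask] = lap[mask] * np.log(rho[mask] / rho0[mask])
        return integrate(grid, vals)
    if which == 2:
        lap = field.lap_rho(grid.points)
        vals[mask] = lap[mask]
        for a in range(partition.natoms):
            m = mask & (partition.rho0_atom[a] > DENSITY_FLOOR)
            vals[m] -= (
                partition.weights[a][m]
                * rho[m]
                * partition.lap0_atom[a][m]
                / partition.rho0_atom[a][m]
            )
        return integrate(grid, vals)
    grad = field.grad_rho(grid.points)
    diff = np.zeros_like(grad)
    diff[mask] = (
        grad[mask] / rho[mask, None] - partition.grad0_promol[mask] / rho0[mask, None]
    )
    vals[mask] = rho[mask] * np.einsum("ni,ni->n", diff[mask], diff[mask])
    return integrate(grid, vals)


def compute_all(
    geom: Geometry,
    field: DensityField,
    refs: dict[str, AtomReference] | None = None,
    grid: Quadrature | None = None,
) -> ITAVector:
    """Evaluate all eleven descriptors in one pass over the grid.

    The reference density rho0 is the promolecule built from ``refs``. S_GBP
    is None when the field lacks orbital densities.
    """
    from .grids import build_grid

    if refs is None:
        refs = load_atom_references()
    if grid is None:
        grid = build_grid(geom)
    part = hirshfeld(geom, refs, field, grid)
    ref = _PromolProxy(part)
    sgbp = gbp_entropy(field, grid) if field.has_orbitals else None
    return ITAVector(
        SS=shannon_entropy(field, grid),
        IF=fisher_information(field, grid),
        SGBP=sgbp,
        E2=onicescu(field, grid, 2),
        E3=onicescu(field, grid, 3),
        R2r=relative_renyi_integral(field, ref, grid, 2),
        R3r=relative_renyi_integral(field, ref, grid, 3),
        IG=information_gain(field, ref, grid),
        G1=relative_fisher_g(part, field, grid, 1),
        G2=relative_fisher_g(part, field, grid, 2),
        G3=relative_fisher_g(part, field, grid, 3),
    )


class _PromolProxy(DensityField):
    """Exposes a HirshfeldPartition's cached promolecular density as a field."""

    def __init__(self, part: HirshfeldPartition):
        self._part = part
        self.n_electrons = float("nan")

    def rho(self, points: np.ndarray) -> np.ndarray:
        if points is not self._part.grid.points:
            raise ContractError("promolecule proxy only valid on its own grid")
        return self._part.rho0_promol
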