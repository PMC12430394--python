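"""Generalized energy-based fragmentation (GEBF).

The total energy of a large cluster is assembled as a linear combination of
embedded-subsystem energies,

    E_tot = sum_m C_m E~_m - (sum_m C_m - 1) * sum_A sum_{B>A} Q_A Q_B / R_AB,

where the primitive subsystems (each fragment plus its neighbors within the
distance threshold zeta, at most gamma_max fragments) carry C_m = +1 and the
derivative subsystems with their signed integer coefficients are generated by
the principle of inclusion and exclusion, so that every fragment is counted
exactly once: sum_{m: f in S_m} C_m = 1.

The point-charge correction applies to total-energy assembly only; the
correlation-energy combination (``gebf_lr_correlation``) is sum_m C_m eps_m,
the classical charge term carrying no correlation component.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_TO_BOHR
from .errors import ContractError
from .geometry import Geometry
from .regression import LinearModel, predict

__all__ = [
    "Subsystem",
    "FragmentationPlan",
    "ChargeSet",
    "build_plan",
    "assemble_energy",
    "gebf_lr_correlation",
]

DEFAULT_ZETA_ANGSTROM = 4.0
DEFAULT_GAMMA_MAX = 6


@dataclass(frozen=True)
class Subsystem:
    fragments: frozenset[int]
    coefficient: int
    kind: str  # "primitive" | "derivative"


@dataclass(frozen=True)
class FragmentationPlan:
    """Fragments, subsystems with inclusion-exclusion coefficients, parameters."""

    fragments: tuple[tuple[int, ...], ...]  # atom indices per fragment
    subsystems: tuple[Subsystem, ...]
    zeta_angstrom: float
    gamma_max: int

    def __post_init__(self) -> None:
        covered = set()
        for s in self.subsystems:
            covered |= s.fragments
        if covered != set(range(len(self.fragments))):
            raise ContractError("every fragment must appear in at least one subsystem")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([s.coefficient for s in self.subsystems], dtype=int)

    def counting_vector(self) -> np.ndarray:
        """sum_{m: f in S_m} C_m per fragment; all ones for a valid plan."""
        counts = np.zeros(len(self.fragments), dtype=int)
        for s in self.subsystems:
            for f in s.fragments:
                counts[f] += s.coefficient
        return counts

    def subsystem_atoms(self, m: int) -> tuple[int, ...]:
        atoms: list[int] = []
        for f in sorted(self.subsystems[m].fragments):
            atoms.extend(self.fragments[f])
        return tuple(atoms)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "zeta_angstrom": self.zeta_angstrom,
            "gamma_max": self.gamma_max,
            "fragments": [list(f) for f in self.fragments],
            "subsystems": [
                {
                    "fragments": sorted(s.fragments),
                    "coefficient": s.coefficient,
                    "kind": s.kind,
                }
                for s in self.subsystems
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FragmentationPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            fragments=tuple(tuple(f) for f in d["fragments"]),
            subsystems=tuple(
                Subsystem(frozenset(s["fragments"]), int(s["coefficient"]), s["kind"])
                for s in d["subsystems"]
            ),
            zeta_angstrom=float(d["zeta_angstrom"]),
            gamma_max=int(d["gamma_max"]),
        )


@dataclass(frozen=True)
class ChargeSet:
    """Atomic point charges Q_A (a.u.) for the embedding correction."""

    charges: tuple[float, ...]

    @classmethod
    def zeros(cls, natoms: int) -> "ChargeSet":
        return cls(tuple(0.0 for _ in range(natoms)))


def _fragment_distances(geom: Geometry) -> np.ndarray:
    """Minimal interatomic distance between every fragment pair (bohr)."""
    nfrag = geom.nfragments
    dist = geom.distance_matrix()
    out = np.zeros((nfrag, nfrag))
    members = [geom.fragment_atoms(f) for f in range(nfrag)]
    for a in range(nfrag):
        for b in range(a + 1, nfrag):
            d = dist[np.ix_(members[a], members[b])].min()
            out[a, b] = out[b, a] = d
    return out


def _sort_key(s: frozenset[int]) -> tuple:
    return (-len(s), tuple(sorted(s)))


def build_plan(
    geom: Geometry,
    zeta: float = DEFAULT_ZETA_ANGSTROM,
    gamma_max: int = DEFAULT_GAMMA_MAX,
) -> FragmentationPlan:
    """Construct primitive and derivative subsystems for a fragmented geometry.

    zeta is the neighbor distance threshold in Angstrom (converted to bohr for
    the minimal-interatomic-distance test); gamma_max caps the number of
    fragments per subsystem, keeping the nearest neighbors (ties broken by
    lower fragment index). Derivative coefficients come from the inclusion-
    exclusion recursion on the intersection closure of the primitive sets,
    processed in decreasing size.
    """
    if geom.fragment_of is None:
        raise ContractError("geometry has no fragment assignment")
    if zeta <= 0:
        raise ContractError("zeta must be positive")
    if gamma_max < 1:
        raise ContractError("gamma_max must be >= 1")
    zeta_bohr = zeta * ANGSTROM_TO_BOHR
    nfrag = geom.nfragments
    fdist = _fragment_distances(geom)

    primitives: list[frozenset[int]] = []
    for f in range(nfrag):
        neighbors = [g for g in range(nfrag) if g != f and fdist[f, g] <= zeta_bohr]
        if len(neighbors) + 1 > gamma_max:
            warnings.warn(
                f"primitive subsystem of fragment {f} truncated to its "
                f"{gamma_max - 1} nearest neighbors (gamma_max={gamma_max})",
                stacklevel=2,
            )
            neighbors.sort(key=lambda g: (fdist[f, g], g))
            neighbors = neighbors[: gamma_max - 1]
        primitives.append(frozenset({f, *neighbors}))

    # drop primitives contained in another retained primitive (keep first of equals)
    keep: list[frozenset[int]] = []
    for i, p in enumerate(primitives):
        redundant = any(
            (p < q) or (p == q and j < i)
            for j, q in enumerate(primitives)
            if j != i
        )
        if not redundant:
            keep.append(p)
    primitives = sorted(set(keep), key=_sort_key)

    # intersection closure
    closure: set[frozenset[int]] = set(primitives)
    frontier = set(primitives)
    while frontier:
        new: set[frozenset[int]] = set()
        for s in frontier:
            for p in primitives:
                inter = s & p
                if inter and inter not in closure and inter not in new:
                    new.add(inter)
        closure |= new
        frontier = new

    # coefficients: sum over supersets in the closure equals 1 for every member,
    # solved by the recursion C_S = 1 - sum_{T strict superset of S} C_T in
    # decreasing-size order
    ordered = sorted(closure, key=_sort_key)
    coeff: dict[frozenset[int], int] = {}
    for s in ordered:
        coeff[s] = 1 - sum(coeff[t] for t in coeff if s < t)

    prim_set = set(primitives)
    subsystems = [
        Subsystem(s, coeff[s], "primitive" if s in prim_set else "derivative")
        for s in ordered
        if coeff[s] != 0 or s in prim_set
    ]
    return FragmentationPlan(
        fragments=tuple(geom.fragment_atoms(f) for f in range(nfrag)),
        subsystems=tuple(subsystems),
        zeta_angstrom=float(zeta),
        gamma_max=int(gamma_max),
    )


def assemble_energy(
    plan: FragmentationPlan,
    energies: np.ndarray,
    geom: Geometry | None = None,
    charges: ChargeSet | None = None,
) -> float:
    """Total energy: sum_m C_m E~_m minus the point-charge double-counting term.

    With no charges (or all zero) the correction vanishes and the result is
    the plain coefficient-weighted sum.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.shape != (len(plan.subsystems),):
        raise ContractError(
            f"expected {len(plan.subsystems)} subsystem energies, got {energies.shape}"
        )
    c = plan.coefficients
    total = float(c @ energies)
    if charges is not None and any(q != 0.0 for q in charges.charges):
        if geom is None:
            raise ContractError("geometry required for the point-charge correction")
        q = np.asarray(charges.charges, dtype=float)
        if len(q) != geom.natoms:
            raise ContractError("one charge per atom required")
        dist = geom.distance_matrix()
        iu = np.triu_indices(geom.natoms, k=1)
        pair_sum = float(np.sum(q[iu[0]] * q[iu[1]] / dist[iu]))
        total -= (int(c.sum()) - 1) * pair_sum
    return total


def gebf_lr_correlation(
    plan: FragmentationPlan, subsystem_ita: np.ndarray, model: LinearModel
) -> float:
    """Correlation energy from per-subsystem descriptor values: sum_m C_m predict(x_m)."""
    x = np.asarray(subsystem_ita, dtype=float)
    if x.shape != (len(plan.subsystems),):
        raise ContractError(
            f"expected {len(plan.subsystems)} descriptor values, got {x.shape}"
        )
    return float(plan.coefficients @ predict(model, x))
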