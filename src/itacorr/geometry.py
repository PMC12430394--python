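"""Molecular geometries: XYZ I/O and bond-graph fragment detection.

Coordinates are stored in bohr; XYZ files are read and written in Angstrom
(the standard two-header-line dialect).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .elements import BOND_FACTOR, covalent_radius_bohr
from .errors import ContractError, ParseError


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: element symbols, Cartesian centers (bohr), charge.

    ``fragment_of`` optionally maps each atom index to a fragment index; when
    present, fragment indices must form a contiguous 0-based range covering
    all atoms.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (natoms, 3), bohr
    charge: int = 0
    fragment_of: tuple[int, ...] | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ContractError(f"coords must be (natoms, 3); got {coords.shape}")
        if len(self.elements) == 0:
            raise ContractError("geometry must contain at least one atom")
        if coords.shape[0] != len(self.elements):
            raise ContractError("coords/elements length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ContractError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.fragment_of is not None:
            frag = tuple(int(f) for f in self.fragment_of)
            if len(frag) != len(self.elements):
                raise ContractError("fragment_of length mismatch")
            if sorted(set(frag)) != list(range(max(frag) + 1)):
                raise ContractError("fragment indices must form a contiguous 0-based range")
            object.__setattr__(self, "fragment_of", frag)

    @property
    def natoms(self) -> int:
        return len(self.elements)

    @property
    def nfragments(self) -> int:
        if self.fragment_of is None:
            raise ContractError("fragments not assigned; call detect_fragments first")
        return max(self.fragment_of) + 1

    def fragment_atoms(self, ifrag: int) -> tuple[int, ...]:
        if self.fragment_of is None:
            raise ContractError("fragments not assigned")
        return tuple(i for i, f in enumerate(self.fragment_of) if f == ifrag)

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def translated(self, shift: Sequence[float]) -> "Geometry":
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))


def read_xyz(path: str | Path, charge: int = 0) -> Geometry:
    """Read a standard XYZ file (Angstrom) into a Geometry (bohr)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: malformed atom-count line: {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise ParseError(
            f"{path}: count line declares {natoms} atoms but only {len(body)} atom lines found"
        )
    elements: list[str] = []
    coords = np.empty((natoms, 3))
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{i + 3}: malformed coordinate line: {line!r}")
        elements.append(parts[0])
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}:{i + 3}: malformed coordinate line: {line!r}") from None
    return Geometry(tuple(elements), coords * ANGSTROM_TO_BOHR, charge=charge, comment=comment)


def write_xyz(geom: Geometry, path: str | Path) -> None:
    """Write a Geometry to XYZ (Angstrom); inverse of :func:`read_xyz`."""
    lines = [str(geom.natoms), geom.comment]
    for el, xyz in zip(geom.elements, geom.coords * BOHR_TO_ANGSTROM):
        lines.append(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def detect_fragments(geom: Geometry) -> Geometry:
    """Assign fragments as connected components of the covalent bond graph.

    Atoms bond when their distance is below ``BOND_FACTOR`` times the sum of
    covalent radii. Fragments are numbered deterministically by the lowest
    atom index they contain.
    """
    n = geom.natoms
    radii = np.array([covalent_radius_bohr(el) for el in geom.elements])
    dist = geom.distance_matrix()
    cutoff = BOND_FACTOR * (radii[:, None] + radii[None, :])
    bonded = (dist < cutoff) & ~np.eye(n, dtype=bool)

    labels = [-1] * n
    nfrag = 0
    for start in range(n):  # ascending start => numbering by lowest member index
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = nfrag
        while stack:
            a = stack.pop()
            for b in np.nonzero(bonded[a])[0]:
                if labels[b] == -1:
                    labels[b] = nfrag
                    stack.append(int(b))
        nfrag += 1
    return replace(geom, fragment_of=tuple(labels))
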