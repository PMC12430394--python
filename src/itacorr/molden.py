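"""Molden file reader/writer for single-determinant wavefunctions.

Handles the [Atoms] (AU/Angs), [GTO] and [MO] sections plus the spherical
flags ([5D], [7F], [5D7F], [9G]). Only real spherical-harmonic s/p/d shells
are supported; Cartesian d sets (no [5D] flag with d shells present) and f/g
shells are rejected rather than silently mis-normalized.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .errors import ParseError, UnsupportedFormatError
from .geometry import Geometry
from .wavefunction import BasisShell, WavefunctionRecord, _ANGULAR_LETTER

__all__ = ["read_molden", "write_molden"]


def _split_sections(lines: list[str]) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("["):
            name = stripped[1 : stripped.index("]")].lower()
            rest = stripped[stripped.index("]") + 1 :].strip()
            current = name
            sections[current] = [rest] if rest else []
        elif current is not None:
            sections[current].append(line.rstrip())
    return sections


def read_molden(path: str | Path) -> tuple[Geometry, WavefunctionRecord]:
    """Parse a Molden file into a geometry (bohr) and a wavefunction record."""
    path = Path(path)
    sections = _split_sections(path.read_text().splitlines())
    for required in ("atoms", "gto", "mo"):
        if required not in sections:
            raise ParseError(f"{path}: missing [{required.upper()}] section")

    # ---- [Atoms]
    atom_lines = [ln for ln in sections["atoms"] if ln.strip()]
    unit = "angs"
    if atom_lines and atom_lines[0].split()[0].lower() in ("au", "angs", "(au)", "(angs)"):
        unit = atom_lines[0].split()[0].lower().strip("()")
        atom_lines = atom_lines[1:]
    elements: list[str] = []
    coords: list[list[float]] = []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 6:
            raise ParseError(f"{path}: malformed [Atoms] line: {ln!r}")
        elements.append(parts[0])
        coords.append([float(p) for p in parts[3:6]])
    xyz = np.array(coords)
    if unit == "angs":
        xyz *= ANGSTROM_TO_BOHR
    geom = Geometry(tuple(elements), xyz)

    # ---- [GTO]
    shells: list[BasisShell] = []
    lines = [ln for ln in sections["gto"] if ln.strip()]
    i = 0
    has_d_or_higher = False
    while i < len(lines):
        parts = lines[i].split()
        atom_index = int(parts[0]) - 1
        i += 1
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) >= 1 and parts[0].isdigit() and len(parts) <= 2:
                break  # next atom header
            letter = parts[0].lower()
            if letter not in _ANGULAR_LETTER:
                raise ParseError(f"{path}: unknown angular momentum letter {letter!r}")
            l = _ANGULAR_LETTER[letter]
            nprim = int(parts[1])
            exps, coefs = [], []
            for k in range(nprim):
                i += 1
                e, c = lines[i].replace("D", "E").replace("d", "e").split()[:2]
                exps.append(float(e))
                coefs.append(float(c))
            i += 1
            if l >= 2:
                has_d_or_higher = True
            shells.append(BasisShell(atom_index, l, tuple(exps), tuple(coefs)))

    spherical_flags = {"5d", "7f", "5d7f", "9g", "5d10f"}
    spherical = bool(spherical_flags & set(sections))
    if has_d_or_higher and not spherical:
        raise UnsupportedFormatError(
            f"{path}: d shells present without a [5D] spherical flag; "
            "Cartesian d/f sets are not supported"
        )

    # ---- [MO]
    nbasis = sum(sh.nfuncs for sh in shells)
    mo_cols: list[np.ndarray] = []
    occs: list[float] = []
    enes: list[float] = []
    mo_lines = sections["mo"]
    i = 0
    while i < len(mo_lines):
        ln = mo_lines[i].strip()
        if not ln:
            i += 1
            continue
        if "=" in ln:
            key, _, value = ln.partition("=")
            key = key.strip().lower()
            if key == "occup":
                occs.append(float(value))
            elif key == "ene":
                enes.append(float(value))
            i += 1
            continue
        col = np.zeros(nbasis)
        count = 0
        while i < len(mo_lines):
            ln = mo_lines[i].strip()
            if not ln or "=" in ln:
                break
            parts = ln.split()
            try:
                idx = int(parts[0]) - 1
                col[idx] = float(parts[1])
            except (ValueError, IndexError):
                raise ParseError(f"{path}: malformed [MO] coefficient line: {ln!r}") from None
            count += 1
            i += 1
        if count < nbasis:
            raise ParseError(
                f"{path}: truncated [MO] block: {count} coefficients for {nbasis} basis functions"
            )
        mo_cols.append(col)
    if len(occs) != len(mo_cols):
        raise ParseError(f"{path}: {len(occs)} Occup= lines for {len(mo_cols)} MOs")

    record = WavefunctionRecord(
        shells=tuple(shells),
        mo_coefficients=np.column_stack(mo_cols),
        occupations=np.array(occs),
        spherical=True,
        energies=tuple(enes) if len(enes) == len(mo_cols) else None,
    )
    return geom, record


def write_molden(geom: Geometry, record: WavefunctionRecord, path: str | Path) -> None:
    """Write a Molden file ([Atoms] Angs, spherical flags); inverse of read_molden."""
    from .elements import atomic_number

    out = ["[Molden Format]", "[Atoms] Angs"]
    for i, (el, xyz) in enumerate(zip(geom.elements, geom.coords * BOHR_TO_ANGSTROM)):
        out.append(
            f"{el} {i + 1} {atomic_number(el)} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}"
        )
    out.append("[GTO]")
    letters = {v: k for k, v in _ANGULAR_LETTER.items()}
    by_atom: dict[int, list[BasisShell]] = {}
    for sh in record.shells:
        by_atom.setdefault(sh.atom, []).append(sh)
    for atom in sorted(by_atom):
        out.append(f"{atom + 1} 0")
        for sh in by_atom[atom]:
            out.append(f" {letters[sh.l]} {len(sh.exponents)} 1.00")
            for e, c in zip(sh.exponents, sh.coefficients):
                out.append(f"  {e:.10e} {c:.10e}")
        out.append("")
    out.extend(["[5D]", "[7F]", "[MO]"])
    energies = record.energies or tuple(0.0 for _ in record.occupations)
    for imo, (occ, ene) in enumerate(zip(record.occupations, energies)):
        out.append(" Sym= A")
        out.append(f" Ene= {ene:.10f}")
        out.append(" Spin= Alpha")
        out.append(f" Occup= {occ:.10f}")
        for ib in range(record.nbasis):
            out.append(f"   {ib + 1} {record.mo_coefficients[ib, imo]: .12e}")
    Path(path).write_text("\n".join(out) + "\n")
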