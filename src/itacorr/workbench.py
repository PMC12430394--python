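"""Synthetic fixture generators and the end-to-end report runner.

The Gaussian-atom families emulate the homologous series of the study
(polymer repeat units, molecular-cluster sizes): identical pseudo-atoms whose
density is a single normalized s-Gaussian, placed on a line or on a jittered
2-D lattice. Every descriptor has a closed form for one center, and because
all eleven descriptors are extensive, descriptor-vs-size series from these
generators are exactly linear — the idealized limit of the published
descriptor/energy tables.
"""
from __future__ import annotations

import json
import logging
import sys
import tomllib
from pathlib import Path

import numpy as np

from .density import AtomReference, GaussianExpansionField, promolecular_field
from .errors import ConfigurationError, ContractError
from .geometry import Geometry

logger = logging.getLogger(__name__)

__all__ = [
    "gaussian_reference",
    "make_gaussian_system",
    "make_homologous_series",
    "run_report",
]

#: synthetic pseudo-element used by the generators
SYNTH_ELEMENT = "X"


def gaussian_reference(
    exponent: float = 1.0, electrons: float = 1.0
) -> dict[str, AtomReference]:
    """Reference table for the synthetic single-Gaussian pseudo-atom."""
    return {SYNTH_ELEMENT: AtomReference(SYNTH_ELEMENT, (electrons,), (exponent,))}


def make_gaussian_system(
    n_centers: int,
    exponent: float = 1.0,
    electrons_per_center: float = 1.0,
    separation: float = 30.0,
) -> tuple[Geometry, GaussianExpansionField]:
    """Identical Gaussian atoms on a line (bohr spacing), with analytic field.

    For ``n_centers = 1`` every descriptor has a closed form; for separations
    large against 1/sqrt(exponent) the system is a set of non-interacting
    copies and every descriptor is n_centers times the monomer value.
    """
    if n_centers < 1:
        raise ContractError("n_centers must be >= 1")
    if separation < 0:
        raise ContractError("separation must be >= 0")
    coords = np.zeros((n_centers, 3))
    coords[:, 2] = separation * np.arange(n_centers)
    geom = Geometry(
        tuple(SYNTH_ELEMENT for _ in range(n_centers)),
        coords,
        fragment_of=tuple(range(n_centers)),
    )
    refs = gaussian_reference(exponent, electrons_per_center)
    return geom, promolecular_field(geom, refs)


def make_homologous_series(
    family: str,
    n_min: int,
    n_max: int,
    spacing: float,
    seed: int = 0,
) -> list[Geometry]:
    """Geometry series of increasing size for trend and GEBF tests.

    ``chain``: n pseudo-atoms on a line, one fragment each. ``ring_cluster``:
    n three-atom rings (fragments) on a 2-D square lattice with seeded jitter,
    emulating a molecular cluster; identical seeds give identical geometries.
    ``spacing`` is the inter-unit distance in bohr.
    """
    if not (1 <= n_min <= n_max):
        raise ContractError("need 1 <= n_min <= n_max")
    if family == "chain":
        return [make_gaussian_system(n, separation=spacing)[0] for n in range(n_min, n_max + 1)]
    if family != "ring_cluster":
        raise ConfigurationError(f"unknown family {family!r}; use chain or ring_cluster")

    out = []
    for n in range(n_min, n_max + 1):
        rng = np.random.default_rng([seed, n])
        side = int(np.ceil(np.sqrt(n)))
        elements: list[str] = []
        coords: list[np.ndarray] = []
        frag_of: list[int] = []
        ring = np.array(
            [[1.0, 0.0, 0.0], [-0.5, np.sqrt(3) / 2, 0.0], [-0.5, -np.sqrt(3) / 2, 0.0]]
        )
        for f in range(n):
            center = np.array(
                [(f % side) * spacing, (f // side) * spacing, 0.0]
            ) + rng.uniform(-0.1, 0.1, 3) * spacing
            for atom in ring:
                elements.append(SYNTH_ELEMENT)
                coords.append(center + atom)
                frag_of.append(f)
        out.append(Geometry(tuple(elements), np.array(coords), fragment_of=tuple(frag_of)))
    return out


def _task_compute(cfg: dict, outdir: Path) -> list[Path]:
    from .density import load_atom_references
    from .descriptors import compute_all
    from .geometry import read_xyz
    from .grids import build_grid
    from .molden import read_molden
    from .wavefunction import wavefunction_field

    xyz = cfg.get("geometry")
    molden = cfg.get("molden")
    if xyz is None and molden is None:
        raise ConfigurationError("compute task needs 'geometry' or 'molden'")
    if molden is not None:
        _require(Path(molden))
        geom, record = read_molden(molden)
        field = wavefunction_field(record, geom)
    else:
        _require(Path(xyz))
        geom = read_xyz(xyz, charge=int(cfg.get("charge", 0)))
        field = promolecular_field(geom)
    n_radial = int(cfg.get("grid_n_radial", 75))
    n_angular = int(cfg.get("grid_n_angular", 392))
    grid = build_grid(geom, n_radial, n_angular)
    vec = compute_all(geom, field, load_atom_references(), grid)
    out = outdir / "descriptors.csv"
    items = vec.as_dict()
    lines = ["descriptor,value_au"]
    lines += [f"{k},{'' if v is None else repr(v)}" for k, v in items.items()]
    out.write_text("\n".join(lines) + "\n")
    return [out]


def _task_fit(cfg: dict, outdir: Path) -> list[Path]:
    from .regression import fit_all, load_table, summary_frame

    table = cfg.get("table")
    if table is None:
        raise ConfigurationError("fit task needs 'table'")
    if table.endswith(".csv"):
        _require(Path(table))
    dt = load_table(table, target=cfg.get("target", "eps_mp2"))
    models = fit_all(dt)
    out = outdir / "models.json"
    out.write_text(json.dumps({k: m.to_dict() for k, m in models.items()}, indent=1))
    summary = outdir / "summary.csv"
    summary_frame(models).to_csv(summary)
    return [out, summary]


def _task_gebf(cfg: dict, outdir: Path) -> list[Path]:
    from .gebf import build_plan
    from .geometry import detect_fragments, read_xyz

    xyz = cfg.get("geometry")
    if xyz is None:
        raise ConfigurationError("gebf task needs 'geometry'")
    _require(Path(xyz))
    geom = read_xyz(xyz, charge=int(cfg.get("charge", 0)))
    geom = detect_fragments(geom)
    plan = build_plan(
        geom,
        zeta=float(cfg.get("zeta_angstrom", 4.0)),
        gamma_max=int(cfg.get("gamma_max", 6)),
    )
    out = outdir / "plan.json"
    plan.to_json(out)
    return [out]


def _require(path: Path) -> None:
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")


_TASKS = {"compute": _task_compute, "fit": _task_fit, "gebf": _task_gebf}


def run_report(config: str | Path, outdir: str | Path | None = None) -> list[Path]:
    """Run the task described by a TOML config; returns the produced files.

    The config carries a ``task`` key (compute | fit | gebf) plus task inputs;
    physical quantities carry unit suffixes in their key names. A run log with
    package version, grid spec and seeds is always written.
    """
    config = Path(config)
    _require(config)
    cfg = tomllib.loads(config.read_text())
    task = cfg.get("task")
    if task not in _TASKS:
        raise ConfigurationError(
            f"unknown task {task!r}; supported: {sorted(_TASKS)}"
        )
    outdir = Path(outdir) if outdir is not None else config.parent / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    produced = _TASKS[task](cfg, outdir)

    from . import __version__

    log = outdir / "run.log"
    log.write_text(
        "\n".join(
            [
                f"itacorr {__version__} python {sys.version.split()[0]}",
                f"config: {config}",
                f"task: {task}",
                f"grid: n_radial={cfg.get('grid_n_radial', 75)} "
                f"n_angular={cfg.get('grid_n_angular', 392)}",
                f"seed: {cfg.get('seed', 0)}",
                "outputs: " + ", ".join(p.name for p in produced),
            ]
        )
        + "\n"
    )
    return produced + [log]
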