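"""Multicenter numerical integration grids.

Per-atom product grids — Gauss–Chebyshev (second kind) radial points under the
Becke radial map r = R_m (1+x)/(1-x) with an element-dependent scale R_m, times
a Gauss–Legendre(cos theta) x uniform(phi) angular product rule — glued into a
single molecular grid with Becke partition-of-unity weights (three smoothing
iterations, no atomic-radius adjustment).

Supported angular point counts are 2*k^2 (k = number of theta nodes, 2k phi
nodes), exact for spherical harmonics up to degree 2k-1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .elements import bragg_radius_bohr
from .errors import ConfigurationError, ContractError
from .geometry import Geometry

__all__ = ["Quadrature", "build_grid", "integrate", "SUPPORTED_ANGULAR"]

#: angular point count -> number of theta nodes
SUPPORTED_ANGULAR: dict[int, int] = {2 * k * k: k for k in range(4, 41)}

DEFAULT_N_RADIAL = 75
DEFAULT_N_ANGULAR = 392
BECKE_ITERATIONS = 3


@dataclass(frozen=True)
class Quadrature:
    """Grid points (bohr), volume weights (bohr^3) and the owning atom per point."""

    points: np.ndarray  # (npts, 3)
    weights: np.ndarray  # (npts,)
    owner_atom: np.ndarray  # (npts,) int
    spec: tuple[int, int, str]  # (n_radial, n_angular, partition scheme)

    @property
    def npts(self) -> int:
        return len(self.weights)


def _radial_nodes(n_radial: int, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Chebyshev (2nd kind) nodes mapped by r = scale (1+x)/(1-x).

    Returns radii and weights absorbing the Jacobian and the r^2 volume factor,
    so that sum_i w_i f(r_i) ~ int_0^inf f(r) r^2 dr.
    """
    i = np.arange(1, n_radial + 1)
    theta = i * math.pi / (n_radial + 1)
    x = np.cos(theta)
    w_gc = math.pi / (n_radial + 1) * np.sin(theta) ** 2
    r = scale * (1.0 + x) / (1.0 - x)
    drdx = 2.0 * scale / (1.0 - x) ** 2
    w = w_gc / np.sqrt(1.0 - x**2) * drdx * r**2
    order = np.argsort(r)  # ascending radii for a stable, documented ordering
    return r[order], w[order]


def _angular_nodes(n_angular: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere product rule; weights sum to 4 pi."""
    if n_angular not in SUPPORTED_ANGULAR:
        supported = sorted(SUPPORTED_ANGULAR)
        raise ConfigurationError(
            f"unsupported angular point count {n_angular}; supported: {supported}"
        )
    k = SUPPORTED_ANGULAR[n_angular]
    mu, w_mu = np.polynomial.legendre.leggauss(k)
    nphi = 2 * k
    phi = 2.0 * math.pi * (np.arange(nphi) + 0.5) / nphi
    w_phi = 2.0 * math.pi / nphi
    sin_t = np.sqrt(1.0 - mu**2)
    dirs = np.empty((k * nphi, 3))
    wts = np.empty(k * nphi)
    idx = 0
    for j in range(k):
        dirs[idx : idx + nphi, 0] = sin_t[j] * np.cos(phi)
        dirs[idx : idx + nphi, 1] = sin_t[j] * np.sin(phi)
        dirs[idx : idx + nphi, 2] = mu[j]
        wts[idx : idx + nphi] = w_mu[j] * w_phi
        idx += nphi
    return dirs, wts


def _becke_smooth(mu: np.ndarray) -> np.ndarray:
    f = mu
    for _ in range(BECKE_ITERATIONS):
        f = 1.5 * f - 0.5 * f**3
    return 0.5 * (1.0 - f)


def _becke_weights(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Partition-of-unity cell weights w_A(r) for every atom at every point."""
    natom = len(centers)
    dist = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=-1)  # (n, A)
    cell = np.ones((len(points), natom))
    for a in range(natom):
        for b in range(natom):
            if a == b:
                continue
            r_ab = np.linalg.norm(centers[a] - centers[b])
            mu = (dist[:, a] - dist[:, b]) / r_ab
            cell[:, a] *= _becke_smooth(mu)
    total = cell.sum(axis=1)
    return cell / total[:, None]


def build_grid(
    geom: Geometry,
    n_radial: int = DEFAULT_N_RADIAL,
    n_angular: int = DEFAULT_N_ANGULAR,
) -> Quadrature:
    """Build the molecular integration grid for a geometry.

    Point ordering is deterministic: atom-major, then radial shell (ascending
    radius), then angular node.
    """
    if n_radial < 20:
        raise ConfigurationError("n_radial must be at least 20")
    dirs, w_ang = _angular_nodes(n_angular)
    nang = len(w_ang)

    all_pts, all_wts, all_owner = [], [], []
    for ia, (el, center) in enumerate(zip(geom.elements, geom.coords)):
        radii, w_rad = _radial_nodes(n_radial, bragg_radius_bohr(el))
        pts = center[None, None, :] + radii[:, None, None] * dirs[None, :, :]
        wts = w_rad[:, None] * w_ang[None, :]
        all_pts.append(pts.reshape(-1, 3))
        all_wts.append(wts.reshape(-1))
        all_owner.append(np.full(n_radial * nang, ia, dtype=int))

    points = np.vstack(all_pts)
    weights = np.concatenate(all_wts)
    owner = np.concatenate(all_owner)

    if geom.natoms > 1:
        becke = _becke_weights(points, geom.coords)
        weights = weights * becke[np.arange(len(points)), owner]

    return Quadrature(points, weights, owner, (n_radial, n_angular, "becke"))


def integrate(grid: Quadrature, values: np.ndarray) -> float:
    """Weighted sum over grid points, in deterministic point-index order."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.weights.shape:
        raise ContractError(
            f"values shape {values.shape} does not match grid ({grid.weights.shape})"
        )
    return float(np.add.reduce(grid.weights * values))


def becke_atom_weights(grid: Quadrature, geom: Geometry) -> np.ndarray:
    """Becke cell weights w_A at every grid point (npts, natoms); rows sum to 1."""
    if geom.natoms == 1:
        return np.ones((grid.npts, 1))
    return _becke_weights(grid.points, geom.coords)
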