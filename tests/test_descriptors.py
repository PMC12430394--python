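import math

import numpy as np
import pytest

from itacorr.constants import GBP
from itacorr.density import AtomReference, GaussianExpansionField
from itacorr.descriptors import (
    compute_all,
    fisher_information,
    gbp_entropy,
    hirshfeld,
    information_gain,
    onicescu,
    relative_fisher_g,
    relative_renyi_entropy,
    relative_renyi_integral,
    shannon_entropy,
)
from itacorr.errors import CapabilityError, DomainError
from itacorr.geometry import Geometry
from itacorr.grids import build_grid
from itacorr.workbench import gaussian_reference, make_gaussian_system

from conftest import radial_oracle, unit_gaussian_field


class TFMockField(GaussianExpansionField):
    """Gaussian density pretending to be orbital-backed with t(r) = t_TF(r)."""

    has_orbitals = True

    def kinetic_density(self, points):
        return GBP.c_k * self.rho(points) ** (5.0 / 3.0)


# ---------------------------------------------------------------- closed forms
def closed_forms(alpha: float) -> dict[str, float]:
    """Analytic descriptor values for the unit-norm Gaussian density."""
    return {
        "SS": 1.5 * (1 + math.log(math.pi / alpha)),
        "IF": 6.0 * alpha,
        "E2": (alpha / (2 * math.pi)) ** 1.5,
        "E3": alpha**3 / (2 * 3**1.5 * math.pi**3),
    }


@pytest.mark.parametrize("alpha", [1.0, 2.0])
def test_single_gaussian_closed_forms(alpha, one_center_grid):
    field = unit_gaussian_field(alpha)
    exact = closed_forms(alpha)
    assert shannon_entropy(field, one_center_grid) == pytest.approx(exact["SS"], rel=1e-6)
    assert fisher_information(field, one_center_grid) == pytest.approx(exact["IF"], rel=1e-6)
    assert onicescu(field, one_center_grid, 2) == pytest.approx(exact["E2"], rel=1e-6)
    assert onicescu(field, one_center_grid, 3) == pytest.approx(exact["E3"], rel=1e-6)


def test_printed_example_values(one_center_grid):
    f1 = unit_gaussian_field(1.0)
    assert shannon_entropy(f1, one_center_grid) == pytest.approx(3.217095, abs=1e-5)
    assert onicescu(f1, one_center_grid, 2) == pytest.approx(0.063494, abs=1e-6)
    assert onicescu(f1, one_center_grid, 3) == pytest.approx(0.003103, abs=1e-6)


def test_separated_fragment_additivity():
    geom, field = make_gaussian_system(2, exponent=1.0, separation=30.0)
    grid = build_grid(geom)
    assert shannon_entropy(field, grid) == pytest.approx(2 * 3.2170948287741, rel=1e-5)
    assert fisher_information(field, grid) == pytest.approx(12.0, rel=1e-5)


# ------------------------------------------------------------ relative measures
def test_relative_renyi_integral_closed_form(one_center_grid):
    f2, f1 = unit_gaussian_field(2.0), unit_gaussian_field(1.0)
    # Omega_2 = 8/3^(3/2) for exponent-2 vs exponent-1 unit Gaussians
    assert relative_renyi_integral(f2, f1, one_center_grid, 2) == pytest.approx(
        8 / 3**1.5, rel=1e-6
    )


def test_relative_renyi_collapses_to_n(one_center_grid):
    f = unit_gaussian_field(1.0, n_elec=14.0)
    assert relative_renyi_integral(f, f, one_center_grid, 2) == pytest.approx(14.0, rel=1e-6)
    assert relative_renyi_integral(f, f, one_center_grid, 3) == pytest.approx(14.0, rel=1e-6)


def test_relative_renyi_entropy_literal_form(one_center_grid):
    f2, f1 = unit_gaussian_field(2.0), unit_gaussian_field(1.0)
    assert relative_renyi_entropy(f2, f1, one_center_grid, 2) == pytest.approx(
        -math.log10(8 / 3**1.5), abs=1e-6
    )
    one = unit_gaussian_field(1.0)
    assert relative_renyi_entropy(one, one, one_center_grid, 2) == pytest.approx(0.0, abs=1e-8)
    ten = unit_gaussian_field(1.0, n_elec=10.0)
    assert relative_renyi_entropy(ten, ten, one_center_grid, 2) == pytest.approx(-1.0, abs=1e-7)


def test_renyi_order_domain(one_center_grid):
    f = unit_gaussian_field(1.0)
    with pytest.raises(DomainError):
        onicescu(f, one_center_grid, 1)
    with pytest.raises(DomainError):
        relative_renyi_integral(f, f, one_center_grid, 1)


def test_information_gain(one_center_grid):
    f2, f1 = unit_gaussian_field(2.0), unit_gaussian_field(1.0)
    assert information_gain(f2, f1, one_center_grid) == pytest.approx(
        1.5 * math.log(2) - 0.75, rel=1e-6
    )
    assert information_gain(f1, f1, one_center_grid) == pytest.approx(0.0, abs=1e-10)
    # Gibbs inequality for an equinormalized pair
    f3 = unit_gaussian_field(3.0)
    assert information_gain(f3, f1, one_center_grid) >= -1e-8


# ------------------------------------------------------------------- GBP entropy
def test_gbp_thomas_fermi_identity(one_center_grid):
    """With t = t_TF the integrand collapses to (3/2) k c rho: S_GBP = (3/2) c N."""
    field = TFMockField(np.zeros((1, 3)), [2.0], [1.0])
    val = gbp_entropy(field, one_center_grid)
    assert val == pytest.approx(1.5 * GBP.c * 2.0, rel=1e-6)
    assert val == pytest.approx(12.461462, abs=1e-5)


def test_gbp_requires_orbitals(one_center_grid):
    with pytest.raises(CapabilityError):
        gbp_entropy(unit_gaussian_field(1.0), one_center_grid)


def test_gbp_constants_defining_expressions():
    assert GBP.c_k == pytest.approx(0.3 * (3 * math.pi**2) ** (2 / 3), rel=1e-12)
    assert GBP.c == pytest.approx(5 / 3 + math.log(4 * math.pi * GBP.c_k / 3), rel=1e-12)
    assert GBP.c_k == pytest.approx(2.871234, abs=1e-6)
    assert GBP.c == pytest.approx(4.1538205, abs=1e-6)


# --------------------------------------------------------------------- Hirshfeld
def test_hirshfeld_single_atom_weight_is_one(one_center_geom, one_center_grid, synth_refs):
    field = unit_gaussian_field(2.0)
    part = hirshfeld(one_center_geom, synth_refs, field, one_center_grid)
    np.testing.assert_allclose(part.weights, 1.0, atol=1e-14)


def test_hirshfeld_midpoint_symmetry_and_unity():
    geom = Geometry(("X", "X"), np.array([[0.0, 0, 0], [0, 0, 4.0]]))
    refs = gaussian_reference(1.0, 1.0)
    from itacorr.density import promolecular_field

    field = promolecular_field(geom, refs)
    grid = build_grid(geom, n_radial=35, n_angular=50)
    part = hirshfeld(geom, refs, field, grid)
    np.testing.assert_allclose(part.weights.sum(axis=0), 1.0, atol=1e-12)
    assert np.all(part.weights >= 0) and np.all(part.weights <= 1)
    # exactly at the midpoint both atoms get omega = 1/2
    from itacorr.grids import Quadrature

    midgrid = Quadrature(
        np.array([[0.0, 0.0, 2.0]]), np.ones(1), np.zeros(1, dtype=int), (1, 1, "manual")
    )
    midpart = hirshfeld(geom, refs, field, midgrid)
    np.testing.assert_allclose(midpart.weights[:, 0], 0.5, atol=1e-14)
    # sum_A int rho_A = int rho
    from itacorr.grids import integrate

    total = sum(integrate(grid, part.atomic_density(a)) for a in range(2))
    assert total == pytest.approx(integrate(grid, field.rho(grid.points)), abs=1e-10)


# ----------------------------------------------------------- relative Fisher G's
def test_g_descriptors_identity_case(one_center_geom, one_center_grid, synth_refs):
    field = unit_gaussian_field(1.0)
    part = hirshfeld(one_center_geom, synth_refs, field, one_center_grid)
    for which in (1, 2, 3):
        assert relative_fisher_g(part, field, one_center_grid, which) == pytest.approx(
            0.0, abs=1e-8
        )


def test_g_descriptors_closed_forms(one_center_geom, one_center_grid, synth_refs):
    """alpha=2 density against the alpha=1 reference: G1=-6, G2=3, G3=3."""
    field = unit_gaussian_field(2.0)
    part = hirshfeld(one_center_geom, synth_refs, field, one_center_grid)
    assert relative_fisher_g(part, field, one_center_grid, 1) == pytest.approx(-6.0, rel=1e-6)
    assert relative_fisher_g(part, field, one_center_grid, 2) == pytest.approx(3.0, rel=1e-6)
    assert relative_fisher_g(part, field, one_center_grid, 3) == pytest.approx(3.0, rel=1e-6)


def test_g_descriptors_match_radial_oracle(one_center_geom, one_center_grid, synth_refs):
    """Dense 1-D quadrature cross-check of G1 and G2 on the one-center system."""
    a, b = 2.0, 1.0
    field = unit_gaussian_field(a)
    part = hirshfeld(one_center_geom, synth_refs, field, one_center_grid)

    def rho(r, e):
        return (e / math.pi) ** 1.5 * np.exp(-e * r**2)

    def lap(r, e):
        return (4 * e**2 * r**2 - 6 * e) * rho(r, e)

    g1_oracle = radial_oracle(
        lambda r: lap(r, a) * (np.log(rho(r, a)) - np.log(rho(r, b)))
    )
    g2_oracle = radial_oracle(lambda r: lap(r, a) - rho(r, a) * lap(r, b) / rho(r, b))
    assert relative_fisher_g(part, field, one_center_grid, 1) == pytest.approx(
        g1_oracle, rel=1e-6
    )
    assert relative_fisher_g(part, field, one_center_grid, 2) == pytest.approx(
        g2_oracle, rel=1e-6
    )


# ------------------------------------------------------------------- compute_all
def test_compute_all_consistent_with_individual_ops(one_center_geom, synth_refs):
    field = unit_gaussian_field(2.0)
    grid = build_grid(one_center_geom)
    vec = compute_all(one_center_geom, field, synth_refs, grid)
    assert vec.SGBP is None  # no orbitals
    assert vec.SS == pytest.approx(shannon_entropy(field, grid), rel=1e-12)
    assert vec.IF == pytest.approx(fisher_information(field, grid), rel=1e-12)
    assert vec.E2 == pytest.approx(onicescu(field, grid, 2), rel=1e-12)
    assert vec.IG == pytest.approx(1.5 * math.log(2) - 0.75, rel=1e-6)
    assert vec.G1 == pytest.approx(-6.0, rel=1e-6)
    assert vec.G3 == pytest.approx(3.0, rel=1e-6)


def test_compute_all_promolecular_identity(synth_refs, one_center_geom):
    """rho = rho0: I_G and G's vanish, Omega_n = N."""
    field = unit_gaussian_field(1.0)
    vec = compute_all(one_center_geom, field, synth_refs)
    assert vec.IG == pytest.approx(0.0, abs=1e-8)
    assert vec.G1 == pytest.approx(0.0, abs=1e-8)
    assert vec.G2 == pytest.approx(0.0, abs=1e-8)
    assert vec.G3 == pytest.approx(0.0, abs=1e-8)
    assert vec.R2r == pytest.approx(1.0, rel=1e-6)


@pytest.mark.parametrize("m", [2, 3])
def test_extensivity_of_all_descriptors(m, synth_refs):
    """m non-interacting copies: every descriptor m times the monomer value."""
    geom1, field1 = make_gaussian_system(1, exponent=2.0)
    mono = compute_all(geom1, field1, synth_refs)
    geomm, fieldm = make_gaussian_system(m, exponent=2.0, separation=30.0)
    multi = compute_all(geomm, fieldm, synth_refs)
    for name, value in mono.as_dict().items():
        if name == "SGBP":
            continue
        assert getattr(multi, name) == pytest.approx(m * value, rel=1e-5), name
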