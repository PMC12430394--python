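"""GEBF plan construction, inclusion-exclusion coefficients, energy assembly."""
import itertools

import numpy as np
import pytest

from itacorr.constants import ANGSTROM_TO_BOHR
from itacorr.errors import ContractError
from itacorr.gebf import ChargeSet, FragmentationPlan, assemble_energy, build_plan, gebf_lr_correlation
from itacorr.geometry import Geometry
from itacorr.regression import LinearModel
from itacorr.workbench import make_homologous_series

# gamma_max = 2 plans intentionally truncate; the warning is under test elsewhere
pytestmark = pytest.mark.filterwarnings("ignore:primitive subsystem")


def chain_geometry(n: int, spacing_angstrom: float = 3.0) -> Geometry:
    d = spacing_angstrom * ANGSTROM_TO_BOHR
    return Geometry(
        tuple("X" for _ in range(n)),
        np.array([[i * d, 0.0, 0.0] for i in range(n)]),
        fragment_of=tuple(range(n)),
    )


def brute_force_coefficients(primitives: list[frozenset]) -> dict[frozenset, int]:
    """Inclusion-exclusion over all subsets of the primitive family (oracle)."""
    agg: dict[frozenset, int] = {}
    for k in range(1, len(primitives) + 1):
        for combo in itertools.combinations(primitives, k):
            inter = frozenset.intersection(*combo)
            if inter:
                agg[inter] = agg.get(inter, 0) + (-1) ** (k + 1)
    return {s: c for s, c in agg.items() if c != 0}


def test_worked_chain_plan():
    """A-B-C-D with d <= zeta < 2d and gamma_max 2: {AB,BC,CD} +1, {B},{C} -1."""
    plan = build_plan(chain_geometry(4), zeta=4.0, gamma_max=2)
    got = {tuple(sorted(s.fragments)): s.coefficient for s in plan.subsystems}
    assert got == {(0, 1): 1, (1, 2): 1, (2, 3): 1, (1,): -1, (2,): -1}
    kinds = {tuple(sorted(s.fragments)): s.kind for s in plan.subsystems}
    assert kinds[(0, 1)] == "primitive" and kinds[(1,)] == "derivative"
    assert sorted(plan.counting_vector()) == [1, 1, 1, 1]


def test_single_fragment_plan():
    plan = build_plan(chain_geometry(1), zeta=4.0)
    assert len(plan.subsystems) == 1
    assert plan.subsystems[0].coefficient == 1


def test_two_distant_fragments_no_derivatives():
    plan = build_plan(chain_geometry(2, spacing_angstrom=10.0), zeta=4.0)
    assert {tuple(sorted(s.fragments)) for s in plan.subsystems} == {(0,), (1,)}
    assert all(s.coefficient == 1 for s in plan.subsystems)


def test_gamma_max_truncation_warns():
    with pytest.warns(UserWarning, match="truncated"):
        plan = build_plan(chain_geometry(5, spacing_angstrom=1.0), zeta=4.0, gamma_max=3)
    assert max(len(s.fragments) for s in plan.subsystems) <= 3
    assert sorted(plan.counting_vector()) == [1] * 5


def test_assembly_single_subsystem():
    plan = build_plan(chain_geometry(1), zeta=4.0)
    assert assemble_energy(plan, np.array([-5.0])) == pytest.approx(-5.0, abs=0)


def test_assembly_exact_on_additive_model():
    e_frag = (-1.0, -2.0, -3.0, -4.0)
    plan = build_plan(chain_geometry(4), zeta=4.0, gamma_max=2)
    e = np.array([sum(e_frag[f] for f in s.fragments) for s in plan.subsystems])
    assert assemble_energy(plan, e) == pytest.approx(-10.0, abs=1e-12)


def test_assembly_charge_correction():
    geom = Geometry(
        ("X", "X"), np.array([[0.0, 0, 0], [10.0, 0, 0]]), fragment_of=(0, 1)
    )
    plan = build_plan(geom, zeta=4.0)
    val = assemble_energy(plan, np.array([-1.0, -2.0]), geom, ChargeSet((0.1, 0.1)))
    assert val == pytest.approx(-3.001, abs=1e-12)


def test_assembly_contract_errors():
    plan = build_plan(chain_geometry(2), zeta=4.0, gamma_max=2)
    with pytest.raises(ContractError):
        assemble_energy(plan, np.zeros(len(plan.subsystems) + 1))


def test_pairwise_model_exactness():
    """Pairwise interactions within zeta are reproduced exactly when every
    close pair co-occurs in some subsystem."""
    geom = chain_geometry(5, spacing_angstrom=3.0)
    plan = build_plan(geom, zeta=4.0, gamma_max=6)
    e_frag = np.array([-1.0, -2.0, -3.0, -4.0, -5.0])
    v = {(i, i + 1): -0.1 * (i + 1) for i in range(4)}  # nearest-neighbor pairs

    def subsystem_energy(frags):
        fr = sorted(frags)
        e = sum(e_frag[f] for f in fr)
        e += sum(
            val for (a, b), val in v.items() if a in frags and b in frags
        )
        return e

    e = np.array([subsystem_energy(s.fragments) for s in plan.subsystems])
    exact = e_frag.sum() + sum(v.values())
    assert assemble_energy(plan, e) == pytest.approx(exact, abs=1e-12)


def test_coefficients_match_brute_force_on_random_clusters():
    """Aggregated plan coefficients equal the brute-force inclusion-exclusion
    oracle, and single counting holds, on seeded random 2-D clusters."""
    rng = np.random.default_rng(2024)
    for trial in range(40):
        nfrag = int(rng.integers(2, 9))
        centers = rng.uniform(0, 12.0, size=(nfrag, 2))
        coords = np.column_stack([centers, np.zeros(nfrag)])
        geom = Geometry(
            tuple("X" for _ in range(nfrag)), coords, fragment_of=tuple(range(nfrag))
        )
        plan = build_plan(geom, zeta=3.0, gamma_max=10)
        assert np.all(plan.counting_vector() == 1), trial
        primitives = [s.fragments for s in plan.subsystems if s.kind == "primitive"]
        oracle = brute_force_coefficients(primitives)
        got = {
            s.fragments: s.coefficient for s in plan.subsystems if s.coefficient != 0
        }
        assert got == oracle, trial


def test_removing_distant_fragment_leaves_others_unchanged():
    geom = chain_geometry(4, spacing_angstrom=3.0)
    far = Geometry(
        geom.elements + ("X",),
        np.vstack([geom.coords, [[500.0, 0, 0]]]),
        fragment_of=geom.fragment_of + (4,),
    )
    p_small = build_plan(geom, zeta=4.0, gamma_max=2)
    p_big = build_plan(far, zeta=4.0, gamma_max=2)
    small = {(tuple(sorted(s.fragments)), s.coefficient) for s in p_small.subsystems}
    big = {(tuple(sorted(s.fragments)), s.coefficient) for s in p_big.subsystems}
    assert big == small | {((4,), 1)}


def test_coefficients_are_integers():
    for geom in make_homologous_series("ring_cluster", 6, 8, spacing=6.0, seed=3):
        plan = build_plan(geom, zeta=4.0, gamma_max=6)
        for s in plan.subsystems:
            assert isinstance(s.coefficient, int)


def test_correlation_combination_telescopes():
    """With descriptors exactly additive over fragments, the GEBF combination
    equals the direct prediction for the whole system (linearity telescopes)."""
    model = LinearModel(slope=-0.05, intercept=0.0, n_points=5, r_squared=1.0, rmsd=0.0)
    x_frag = np.array([10.0, 11.0, 12.0, 13.0])
    plan = build_plan(chain_geometry(4), zeta=4.0, gamma_max=2)
    x_sub = np.array([sum(x_frag[f] for f in s.fragments) for s in plan.subsystems])
    # intercept 0 so prediction is linear, not affine: exact telescoping
    assert gebf_lr_correlation(plan, x_sub, model) == pytest.approx(
        model.slope * x_frag.sum(), abs=1e-12
    )


def test_correlation_combination_disjoint_fragments():
    model = LinearModel(slope=2.0, intercept=1.0, n_points=3, r_squared=1.0, rmsd=0.0)
    plan = build_plan(chain_geometry(2, spacing_angstrom=10.0), zeta=4.0)
    assert gebf_lr_correlation(plan, np.array([3.0, 4.0]), model) == pytest.approx(
        (2 * 3 + 1) + (2 * 4 + 1), abs=1e-12
    )


def test_plan_json_roundtrip(tmp_path):
    plan = build_plan(chain_geometry(4), zeta=4.0, gamma_max=2)
    p = tmp_path / "plan.json"
    plan.to_json(p)
    back = FragmentationPlan.from_json(p)
    assert back == plan
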