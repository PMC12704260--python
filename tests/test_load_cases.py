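import numpy as np
import pytest

from morphomech import femesh, load_cases, template, verification as V
from morphomech.fe_solver import Material, reaction_force, solve
from morphomech.load_cases import (
    ScenarioSpec,
    bending_case,
    biting_case,
    mechanical_advantage,
    muscle_force,
    scaled_load,
)
from morphomech.morphometrics import TernaryCoord
from morphomech.template import build_outline, hole_area, outline_area


class TestScaledLoad:
    @pytest.mark.parametrize("a_model, expected", [(1.0, 100.0), (2.0, 200.0), (0.5, 50.0)])
    def test_proportional_to_area(self, a_model, expected):
        assert scaled_load(100.0, a_model, 1.0) == pytest.approx(expected)

    def test_invalid_area_rejected(self):
        with pytest.raises(ValueError):
            scaled_load(100.0, -1.0, 1.0)


class TestBendingCase:
    def test_reference_model_gets_reference_load(self, base_mesh):
        A = 20000.0
        bc = bending_case(base_mesh, ScenarioSpec(F_ref=100.0, A_ref=A), A)
        assert len(bc.point_loads) == 1
        node, force = bc.point_loads[0]
        assert node == int(base_mesh.node_sets["snout_tip"][0])
        assert force == pytest.approx((0.0, 100.0))
        assert bc.fixed == [("quadrate", "xy")]

    def test_half_area_halves_load(self, base_mesh):
        bc = bending_case(base_mesh, ScenarioSpec(F_ref=100.0, A_ref=20000.0), 10000.0)
        assert bc.point_loads[0][1][1] == pytest.approx(50.0)

    def test_solve_satisfies_equilibrium(self, base_outline, base_mesh):
        A = outline_area(base_outline)
        bc = bending_case(base_mesh, ScenarioSpec(F_ref=100.0, A_ref=A), A)
        res = solve(base_mesh, Material(), bc=bc)
        assert V.equilibrium_check(res, bc) < 1e-6


class TestMuscleForce:
    def test_tension_times_temporal_area(self, base_outline, base_mesh):
        area = hole_area(base_outline, "temporal")
        assert muscle_force(base_mesh, base_outline, 0.3) == pytest.approx(0.3 * area)

    def test_zero_tension_zero_force(self, base_outline, base_mesh):
        assert muscle_force(base_mesh, base_outline, 0.0) == 0.0

    def test_strictly_increasing_with_braincase(self):
        forces = []
        for b in (0.1, 0.2, 0.3, 0.4):
            p = template.SkullParams(tern=TernaryCoord(0.5 - b + 0.1, 0.4, b), ratio=3.0, length=300.0)
            out = build_outline(p)
            mesh = femesh.triangulate(out, 6.0)
            forces.append(muscle_force(mesh, out, 0.3))
        assert forces == sorted(forces)
        assert len(set(forces)) == len(forces)

    def test_absent_temporal_hole_is_an_error(self):
        p = template.SkullParams(tern=TernaryCoord(0.55, 0.38, 0.07), ratio=3.0, length=300.0)
        out = build_outline(p)
        mesh = femesh.triangulate(out, 6.0)
        with pytest.raises(ValueError, match="braincase"):
            muscle_force(mesh, out, 0.3)


class TestBitingCase:
    def test_equal_division_and_unit_directions(self, base_outline, base_mesh):
        spec = ScenarioSpec(kind="biting", muscle_tension=0.3)
        bc = biting_case(base_mesh, base_outline, spec)
        total = muscle_force(base_mesh, base_outline, 0.3)
        (set_name, forces), = bc.distributed_loads
        assert set_name == "temporal_margin"
        n = len(base_mesh.node_sets["temporal_margin"])
        mags = np.linalg.norm(forces, axis=1)
        assert np.allclose(mags, total / n)
        assert ("quadrate", "xy") in bc.fixed and ("bite", "y") in bc.fixed

    def test_bite_reaction_not_exceeding_muscle_force(self, base_outline, base_mesh):
        spec = ScenarioSpec(kind="biting", muscle_tension=0.3)
        bc = biting_case(base_mesh, base_outline, spec)
        res = solve(base_mesh, Material(), bc=bc)
        total = muscle_force(base_mesh, base_outline, 0.3)
        assert abs(reaction_force(res, "bite")[1]) <= total

    def test_solve_satisfies_equilibrium(self, base_outline, base_mesh):
        bc = biting_case(base_mesh, base_outline, ScenarioSpec(kind="biting"))
        res = solve(base_mesh, Material(), bc=bc)
        assert V.equilibrium_check(res, bc) < 1e-6


class TestMechanicalAdvantage:
    def test_definition(self):
        assert mechanical_advantage(np.array([5.0, 30.0]), 100.0) == pytest.approx(0.3)
        assert mechanical_advantage(np.array([0.0, 0.0]), 50.0) == 0.0

    def test_rigid_lever_oracle(self):
        res = V.lever_oracle(d_in_frac=0.3)
        assert res["rel_err"] < 0.05

    def test_lever_oracle_other_geometry(self):
        res = V.lever_oracle(d_in_frac=0.6)
        assert res["rel_err"] < 0.05

    def test_zero_muscle_rejected(self):
        with pytest.raises(ValueError):
            mechanical_advantage(np.array([0.0, 1.0]), 0.0)


def test_homothety_invariance_of_stress_field():
    """Area-corrected scaling leaves median stresses and MA unchanged."""
    assert V.homothety_check(k=2.0) < 1e-3
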