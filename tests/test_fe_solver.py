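import numpy as np
import pytest

from morphomech import verification as V
from morphomech.fe_solver import (
    BoundaryConditions,
    FEResult,
    Material,
    median_vm,
    reaction_force,
    solve,
    von_mises,
)


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises(5e6, 0, 0) == pytest.approx(5e6)

    def test_pure_shear(self):
        assert von_mises(0, 0, 2e6) == pytest.approx(np.sqrt(3) * 2e6)

    def test_equibiaxial(self):
        assert von_mises(3e6, 3e6, 0) == pytest.approx(3e6)


def _fake_result(vm):
    vm = np.asarray(vm, float)
    return FEResult(
        displacements=np.zeros((1, 2)),
        element_stress=np.zeros((len(vm), 3)),
        von_mises_field=vm,
        median_vm=float(np.median(vm)),
        mean_vm=float(np.mean(vm)),
        reactions={"quadrate": np.array([0.0, 0.0])},
        nodal_reactions=np.zeros((1, 2)),
    )


class TestMedianVM:
    def test_odd_count(self):
        assert median_vm(_fake_result([1, 2, 3])) == pytest.approx(2)

    def test_even_count_averages_middle_pair(self):
        assert median_vm(_fake_result([1, 2, 3, 10])) == pytest.approx(2.5)


def test_reaction_force_unknown_set_raises():
    with pytest.raises(KeyError):
        reaction_force(_fake_result([1.0]), "snout_tip")


class TestPatchTest:
    def test_constant_stress_reproduced_exactly(self):
        res = V.patch_test()
        assert res["max_rel_stress_dev"] < 1e-9
        assert res["median_vm"] == pytest.approx(res["expected_vm"], rel=1e-9)


class TestCantilever:
    def test_tip_deflection_matches_beam_theory(self):
        res = V.cantilever(target_h=0.05)
        assert res["tip_deflection_rel_err"] < 0.03

    def test_root_stress_matches_beam_theory(self):
        res = V.cantilever(target_h=0.05)
        assert res["root_stress_rel_err"] < 0.05


class TestSolveBasics:
    def test_zero_load_zero_response(self, base_mesh):
        bc = BoundaryConditions(fixed=[("quadrate", "xy")])
        res = solve(base_mesh, Material(), bc=bc)
        assert np.abs(res.displacements).max() == 0
        assert np.abs(res.von_mises_field).max() == 0

    def test_linearity_in_load(self, base_mesh):
        tip = int(base_mesh.node_sets["snout_tip"][0])
        bc1 = BoundaryConditions(fixed=[("quadrate", "xy")], point_loads=[(tip, (0.0, 100.0))])
        bc2 = BoundaryConditions(fixed=[("quadrate", "xy")], point_loads=[(tip, (0.0, 200.0))])
        r1 = solve(base_mesh, Material(), bc=bc1)
        r2 = solve(base_mesh, Material(), bc=bc2)
        assert np.allclose(r2.displacements, 2 * r1.displacements, rtol=1e-9, atol=0)
        assert np.allclose(r2.von_mises_field, 2 * r1.von_mises_field, rtol=1e-9)
        assert np.allclose(r2.reactions["quadrate"], 2 * r1.reactions["quadrate"], rtol=1e-9)

    def test_equilibrium(self, base_mesh):
        tip = int(base_mesh.node_sets["snout_tip"][0])
        bc = BoundaryConditions(fixed=[("quadrate", "xy")], point_loads=[(tip, (30.0, 100.0))])
        res = solve(base_mesh, Material(), bc=bc)
        assert V.equilibrium_check(res, bc) < 1e-6

    def test_insufficient_constraints_rejected(self, base_mesh):
        tip = int(base_mesh.node_sets["snout_tip"][0])
        bc = BoundaryConditions(fixed=[("bite", "y")], point_loads=[(tip, (10.0, 0.0))])
        with pytest.raises(ValueError):
            solve(base_mesh, Material(), bc=bc)

    def test_no_constraints_rejected(self, base_mesh):
        with pytest.raises(ValueError):
            solve(base_mesh, Material(), bc=BoundaryConditions())


def test_material_validation():
    with pytest.raises(ValueError):
        Material(E=-1.0)
    with pytest.raises(ValueError):
        Material(nu=0.5)


def test_convergence_of_median_stress():
    """Median von Mises changes < 5% when halving element size from the
    default resolution, for both loading scenarios."""
    from morphomech import template
    from morphomech.morphometrics import TernaryCoord
    from morphomech.pipeline import PipelineConfig, evaluate_model, reference_area

    A = reference_area(PipelineConfig())
    p = template.SkullParams(tern=TernaryCoord(0.6, 0.2, 0.2), ratio=3.0, length=300.0)
    coarse = evaluate_model(p, PipelineConfig(target_h_factor=90), A_ref=A)
    fine = evaluate_model(p, PipelineConfig(target_h_factor=180), A_ref=A)
    for key in ("bending_median_vm", "biting_median_vm"):
        assert abs(fine[key] - coarse[key]) / coarse[key] < 0.05


def test_vm_export(tmp_path, base_mesh):
    from morphomech import load_cases
    from morphomech.fe_solver import export_vm_csv

    bc = BoundaryConditions(
        fixed=[("quadrate", "xy")],
        point_loads=[(int(base_mesh.node_sets["snout_tip"][0]), (0.0, 100.0))],
    )
    res = solve(base_mesh, Material(), bc=bc)
    export_vm_csv(base_mesh, res, tmp_path / "vm.csv")
    data = np.loadtxt(tmp_path / "vm.csv", delimiter=",", skiprows=1)
    assert len(data) == base_mesh.n_elements
    assert (data[:, 2] >= 0).all()
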