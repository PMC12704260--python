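"""Built-in verification battery for the finite-element machinery.

Each check compares the solver against an independent closed form: constant
stress on a uniformly loaded patch, Euler-Bernoulli tip deflection and root
bending stress of a slender cantilever, moment balance of a rigid lever
(mechanical advantage), global equilibrium on the base skull model, and
invariance of the stress field under homothetic scaling with area-corrected
loads.
"""

from __future__ import annotations

import numpy as np

from morphomech import femesh, load_cases, template
from morphomech.fe_solver import BoundaryConditions, Material, solve
from morphomech.morphometrics import TernaryCoord

MM = 1e-3


def rectangle_outline(width: float, height: float, thickness: float = 1.0) -> template.Outline2D:
    """Axis-aligned rectangle in mm, lower-left at the origin."""
    ring = np.array([[0, 0], [width, 0], [width, height], [0, height]], float)
    return template.Outline2D.from_polygon(ring, thickness=thickness)


def _edge_nodes(mesh: femesh.Mesh2D, axis: int, value: float, tol: float = 1e-9) -> np.ndarray:
    idx = np.where(np.abs(mesh.nodes[:, axis] - value) < tol)[0]
    return idx[np.argsort(mesh.nodes[idx, 1 - axis])]


def _consistent_edge_load(mesh, edge_idx, traction_pa, axis_load: int):
    """Nodal forces equivalent to a uniform traction on a straight edge."""
    coords = mesh.nodes[edge_idx] * MM
    t_m = mesh.thickness * MM
    forces = np.zeros((len(edge_idx), 2))
    for i in range(len(edge_idx) - 1):
        seg = np.linalg.norm(coords[i + 1] - coords[i])
        f = traction_pa * t_m * seg / 2
        forces[i, axis_load] += f
        forces[i + 1, axis_load] += f
    return [(int(n), tuple(f)) for n, f in zip(edge_idx, forces)]


def patch_test(target_h: float = 0.25) -> dict:
    """Uniform uniaxial tension on a rectangle: CST must be exact.

    Returns max relative deviation of (sigma_x, sigma_y, tau_xy) from
    (sigma_0, 0, 0) over all elements.
    """
    W, H, sigma0 = 2.0, 1.0, 1.0e6
    outline = rectangle_outline(W, H, thickness=1.0)
    mesh = femesh.triangulate(outline, target_h)
    left = _edge_nodes(mesh, 0, 0.0)
    right = _edge_nodes(mesh, 0, W)
    bottom_left = int(left[0])
    mesh.node_sets["left"] = left
    mesh.node_sets["corner"] = np.array([bottom_left])
    bc = BoundaryConditions(
        fixed=[("left", "x"), ("corner", "y")],
        point_loads=_consistent_edge_load(mesh, right, sigma0, 0),
    )
    res = solve(mesh, Material(), bc=bc)
    dev = np.abs(res.element_stress - np.array([sigma0, 0.0, 0.0])) / sigma0
    return {
        "max_rel_stress_dev": float(dev.max()),
        "median_vm": res.median_vm,
        "expected_vm": sigma0,
    }


def cantilever(target_h: float = 0.05, L: float = 10.0, H: float = 1.0, P: float = 100.0) -> dict:
    """Slender cantilever vs Euler-Bernoulli closed form.

    Root edge on sliding supports (u_x = 0) with the mid-height root node
    pinned vertically, so Poisson contraction is unconstrained and the
    comparison isolates bending.  Tip load applied as a uniform edge
    traction.  Returns relative errors of tip deflection vs P L^3 / 3 E I
    and of the root-fiber bending stress vs the local moment closed form.
    """
    mat = Material()
    outline = rectangle_outline(L, H, thickness=1.0)
    mesh = femesh.triangulate(outline, target_h)
    root = _edge_nodes(mesh, 0, 0.0)
    tip = _edge_nodes(mesh, 0, L)
    mid = root[int(np.argmin(np.abs(mesh.nodes[root, 1] - H / 2)))]
    mesh.node_sets["root"] = root
    mesh.node_sets["mid"] = np.array([int(mid)])
    shear = P / (mesh.thickness * MM * H * MM)  # Pa, uniform over the tip edge
    bc = BoundaryConditions(
        fixed=[("root", "x"), ("mid", "y")],
        point_loads=_consistent_edge_load(mesh, tip, -shear, 1),
    )
    res = solve(mesh, mat, bc=bc)
    tip_mid = tip[int(np.argmin(np.abs(mesh.nodes[tip, 1] - H / 2)))]
    delta = -res.displacements[tip_mid, 1]
    I = (mesh.thickness * MM) * (H * MM) ** 3 / 12
    delta_eb = P * (L * MM) ** 3 / (3 * mat.E * I)

    # root-fiber stress from a linear fit of sigma_x over a thin root slab,
    # referenced to the moment at the slab's centroid line
    cent = mesh.nodes[mesh.triangles].mean(axis=1)
    slab = cent[:, 0] < 3 * target_h
    y = (cent[slab, 1] - H / 2) * MM
    sx = res.element_stress[slab, 0]
    slope = np.sum(sx * y) / np.sum(y * y)
    xbar = float(np.average(cent[slab, 0], weights=np.abs(y))) * MM
    slope_exact = P * (L * MM - xbar) / I
    sigma_root = slope * (H / 2 * MM)
    sigma_exact = 6 * P * (L * MM - xbar) / ((mesh.thickness * MM) * (H * MM) ** 2)
    return {
        "tip_deflection_rel_err": float(abs(delta - delta_eb) / delta_eb),
        "root_stress_rel_err": float(abs(slope - slope_exact) / slope_exact),
        "sigma_root": float(sigma_root),
        "sigma_root_expected": float(sigma_exact),
        "delta": float(delta),
        "delta_expected": float(delta_eb),
    }


def lever_oracle(d_in_frac: float = 0.3, target_h: float = 2.5) -> dict:
    """Rigid-lever mechanical advantage: MA must match d_in / d_out.

    A straight beam pinned at one end, loaded vertically at distance d_in
    from the pivot, with a vertical bite support at distance d_out.  Moment
    balance fixes the reaction ratio independent of elasticity.
    """
    Lb, Hb, F = 100.0, 10.0, 50.0
    outline = rectangle_outline(Lb, Hb, thickness=5.0)
    mesh = femesh.triangulate(outline, target_h)

    def nearest(x, y):
        return int(np.argmin(np.linalg.norm(mesh.nodes - [x, y], axis=1)))

    pivot = nearest(Lb, Hb / 2)
    load_node = nearest(Lb * (1 - d_in_frac), Hb)
    bite_node = nearest(0.0, 0.0)
    mesh.node_sets["pivot"] = np.array([pivot])
    mesh.node_sets["bite"] = np.array([bite_node])
    bc = BoundaryConditions(
        fixed=[("pivot", "xy"), ("bite", "y")],
        point_loads=[(load_node, (0.0, -F))],
    )
    res = solve(mesh, Material(), bc=bc)
    ma = load_cases.mechanical_advantage(res.reactions["bite"], F)
    d_in = mesh.nodes[pivot, 0] - mesh.nodes[load_node, 0]
    d_out = mesh.nodes[pivot, 0] - mesh.nodes[bite_node, 0]
    expected = d_in / d_out
    return {"ma": float(ma), "expected": float(expected), "rel_err": float(abs(ma - expected) / expected)}


def equilibrium_check(result, bc: BoundaryConditions) -> float:
    """Max relative imbalance between reactions and applied loads."""
    applied = bc.total_applied()
    reac = sum(result.reactions.values())
    scale = max(np.linalg.norm(applied), 1e-12)
    return float(np.linalg.norm(applied + reac) / scale)


def homothety_check(config=None, k: float = 2.0) -> float:
    """Relative deviation of the von Mises field under homothetic scaling.

    Scaling length by k (composition, ratio, thickness coefficient fixed)
    with area-corrected loads must leave stresses unchanged.
    """
    from morphomech.pipeline import PipelineConfig, evaluate_model, reference_area

    config = config or PipelineConfig()
    A_ref = reference_area(config)
    base = template.SkullParams(
        tern=TernaryCoord(0.6, 0.2, 0.2), ratio=config.base_ratio, length=config.base_length_mm
    )
    scaled = template.SkullParams(
        tern=TernaryCoord(0.6, 0.2, 0.2), ratio=config.base_ratio, length=k * config.base_length_mm
    )
    m0 = evaluate_model(base, config, A_ref=A_ref)
    m1 = evaluate_model(scaled, config, A_ref=A_ref)
    devs = [
        abs(m1[key] - m0[key]) / m0[key]
        for key in ("bending_median_vm", "biting_median_vm", "mechanical_advantage")
    ]
    return float(max(devs))


def run_checks(config=None) -> dict[str, tuple[bool, str]]:
    """Fast verification suite used by ``morphomech check``."""
    from morphomech.pipeline import PipelineConfig, evaluate_model, reference_area

    config = config or PipelineConfig()
    out: dict[str, tuple[bool, str]] = {}

    p = patch_test()
    out["patch_test"] = (p["max_rel_stress_dev"] < 1e-8, f"max stress deviation {p['max_rel_stress_dev']:.2e}")

    c = cantilever(target_h=0.1)
    out["cantilever_deflection"] = (
        c["tip_deflection_rel_err"] < 0.05,
        f"tip deflection within {100 * c['tip_deflection_rel_err']:.2f}% of beam theory",
    )

    lv = lever_oracle()
    out["lever_mechanical_advantage"] = (lv["rel_err"] < 0.05, f"MA {lv['ma']:.3f} vs lever {lv['expected']:.3f}")

    # equilibrium on the base skull under bending
    base = template.SkullParams(
        tern=TernaryCoord(0.6, 0.2, 0.2), ratio=config.base_ratio, length=config.base_length_mm
    )
    outline = template.build_outline(base)
    A = template.outline_area(outline)
    mesh = femesh.triangulate(outline, config.base_length_mm / config.target_h_factor)
    spec = load_cases.ScenarioSpec(F_ref=config.F_ref_n, A_ref=A)
    bc = load_cases.bending_case(mesh, spec, A)
    res = solve(mesh, config.material, bc=bc)
    imb = equilibrium_check(res, bc)
    out["global_equilibrium"] = (imb < 1e-6, f"relative imbalance {imb:.2e}")

    h = homothety_check(config)
    out["homothety_invariance"] = (h < 1e-3, f"max metric deviation {h:.2e} under 2x scaling")
    return out
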