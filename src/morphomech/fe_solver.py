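"""Linear elastic plane-stress finite elements on triangle meshes.

Constant-strain triangles (CST): each element carries a uniform strain and
stress, which makes the element-wise von Mises field and its median direct
analogues of element-based solver output.  The global system is symmetric
positive definite once rigid-body modes are removed by the boundary
conditions and is solved with a direct sparse factorization.

Units: the mesh is in mm at the interface; assembly converts coordinates and
thickness to metres once, so displacements come out in m, stresses in Pa,
forces in N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from morphomech.femesh import Mesh2D

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class Material:
    """Isotropic linear elastic material (plane stress)."""

    E: float = 15.00e9   # Pa; crocodilian bone
    nu: float = 0.29

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not (0 <= self.nu < 0.5):
            raise ValueError("nu must be in [0, 0.5)")

    def d_matrix(self) -> np.ndarray:
        """Plane-stress constitutive matrix (3x3, Pa)."""
        c = self.E / (1 - self.nu**2)
        return c * np.array(
            [[1, self.nu, 0], [self.nu, 1, 0], [0, 0, (1 - self.nu) / 2]]
        )


@dataclass
class BoundaryConditions:
    """Constraints and loads referencing mesh node sets / node indices.

    ``fixed``: list of (node_set_name, axes) where axes is a string drawn
    from "x", "y", "xy".  ``point_loads``: list of (node_index, (Fx, Fy) N).
    ``distributed_loads``: list of (node_set_name, per-node (n, 2) force
    array N).
    """

    fixed: list[tuple[str, str]] = field(default_factory=list)
    point_loads: list[tuple[int, tuple[float, float]]] = field(default_factory=list)
    distributed_loads: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def total_applied(self) -> np.ndarray:
        t = np.zeros(2)
        for _, f in self.point_loads:
            t += np.asarray(f, float)
        for _, fs in self.distributed_loads:
            t += np.asarray(fs, float).sum(axis=0)
        return t


@dataclass
class FEResult:
    """Solution fields of one static solve."""

    displacements: np.ndarray           # (n, 2) m
    element_stress: np.ndarray          # (m, 3) Pa: sigma_x, sigma_y, tau_xy
    von_mises_field: np.ndarray         # (m,) Pa
    median_vm: float                    # Pa
    mean_vm: float                      # Pa
    reactions: dict[str, np.ndarray]    # per constrained set, (Fx, Fy) N
    nodal_reactions: np.ndarray         # (n, 2) N, nonzero only at constraints


def von_mises(sx, sy, txy):
    """Plane-stress equivalent (von Mises) stress."""
    sx, sy, txy = np.asarray(sx, float), np.asarray(sy, float), np.asarray(txy, float)
    return np.sqrt(sx**2 + sy**2 - sx * sy + 3 * txy**2)


def median_vm(result: FEResult) -> float:
    """Unweighted median of the element von Mises values."""
    if result.von_mises_field.size == 0:
        raise ValueError("no elements")
    return float(np.median(result.von_mises_field))


def reaction_force(result: FEResult, set_name: str) -> np.ndarray:
    """Summed reaction force (N) over a constrained node set."""
    if set_name not in result.reactions:
        raise KeyError(f"set '{set_name}' was not constrained")
    return result.reactions[set_name]


def _element_matrices(nodes_m: np.ndarray, tris: np.ndarray, D: np.ndarray, t_m: float):
    """Vectorized CST B-matrices, areas and stiffness blocks."""
    p = nodes_m[tris]                                  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2])
    m = len(tris)
    B = np.zeros((m, 3, 6))
    inv2A = 1.0 / (2 * area)
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i] * inv2A
        B[:, 1, 2 * i + 1] = c[:, i] * inv2A
        B[:, 2, 2 * i] = c[:, i] * inv2A
        B[:, 2, 2 * i + 1] = b[:, i] * inv2A
    # k_e = t * A * B^T D B
    ke = t_m * area[:, None, None] * np.einsum("mji,jk,mkl->mil", B, D, B)
    return B, area, ke


def solve(
    mesh: Mesh2D,
    material: Material,
    thickness: float | None = None,
    bc: BoundaryConditions | None = None,
) -> FEResult:
    """Static plane-stress solve.

    ``thickness`` is in mm (defaults to the mesh's stored thickness).
    Raises on singular systems (insufficient constraints) or non-finite
    solutions.  Global equilibrium (reactions balancing applied loads) is an
    invariant of the returned result.
    """
    if bc is None or not bc.fixed:
        raise ValueError("boundary conditions with at least one fixed set are required")
    t_mm = mesh.thickness if thickness is None else thickness
    if t_mm <= 0:
        raise ValueError("thickness must be > 0")
    nodes_m = mesh.nodes * MM
    t_m = t_mm * MM
    D = material.d_matrix()
    tris = mesh.triangles
    B, area, ke = _element_matrices(nodes_m, tris, D, t_m)
    if (area <= 0).any():
        raise ValueError("mesh contains non-CCW or degenerate triangles")

    n = mesh.n_nodes
    ndof = 2 * n
    dofs = np.empty((len(tris), 6), dtype=int)
    dofs[:, 0::2] = 2 * tris
    dofs[:, 1::2] = 2 * tris + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    f = np.zeros(ndof)
    for node, force in bc.point_loads:
        f[2 * node] += force[0]
        f[2 * node + 1] += force[1]
    for set_name, forces in bc.distributed_loads:
        idx = mesh.node_sets[set_name]
        forces = np.asarray(forces, float)
        if forces.shape != (len(idx), 2):
            raise ValueError(f"distributed load on '{set_name}' must be ({len(idx)}, 2)")
        np.add.at(f, 2 * idx, forces[:, 0])
        np.add.at(f, 2 * idx + 1, forces[:, 1])
    if not np.isfinite(f).all():
        raise ValueError("non-finite loads")

    fixed_dofs: list[int] = []
    set_dofs: dict[str, list[int]] = {}
    for set_name, axes in bc.fixed:
        idx = mesh.node_sets[set_name]
        sd = []
        if "x" in axes:
            sd += list(2 * idx)
        if "y" in axes:
            sd += list(2 * idx + 1)
        if not sd:
            raise ValueError(f"fixed set '{set_name}' constrains no axis")
        set_dofs[set_name] = sd
        fixed_dofs += sd
    fixed_dofs = np.unique(fixed_dofs)
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)

    Kff = K[free][:, free].tocsc()
    u = np.zeros(ndof)
    try:
        u_free = spsolve(Kff, f[free])
    except RuntimeError as exc:  # pragma: no cover - umfpack path
        raise ValueError(f"singular system: {exc}") from exc
    if not np.isfinite(u_free).all():
        raise ValueError("singular or ill-conditioned system (non-finite solution)")
    # guard against a positive-semidefinite system that spsolve "solved"
    resid = np.abs(Kff @ u_free - f[free]).max()
    scale = max(np.abs(f).max(), 1.0)
    if resid > 1e-6 * scale:
        raise ValueError("solver residual too large; constraints likely insufficient")
    u[free] = u_free

    r_all = K @ u - f
    nodal_reactions = np.zeros((n, 2))
    mask = np.zeros(ndof, bool)
    mask[fixed_dofs] = True
    nodal_reactions[:, 0] = np.where(mask[0::2], r_all[0::2], 0.0)
    nodal_reactions[:, 1] = np.where(mask[1::2], r_all[1::2], 0.0)
    reactions = {}
    for set_name, sd in set_dofs.items():
        rx = sum(r_all[d] for d in sd if d % 2 == 0)
        ry = sum(r_all[d] for d in sd if d % 2 == 1)
        reactions[set_name] = np.array([rx, ry])

    ue = u[dofs]                                     # (m, 6)
    stress = np.einsum("ij,mjk,mk->mi", D, B, ue)    # (m, 3)
    vm = von_mises(stress[:, 0], stress[:, 1], stress[:, 2])
    return FEResult(
        displacements=u.reshape(n, 2),
        element_stress=stress,
        von_mises_field=vm,
        median_vm=float(np.median(vm)),
        mean_vm=float(np.mean(vm)),
        reactions=reactions,
        nodal_reactions=nodal_reactions,
    )


def export_vm_csv(mesh: Mesh2D, result: FEResult, path) -> None:
    """Per-element centroid + von Mises stress as CSV."""
    cent = mesh.nodes[mesh.triangles].mean(axis=1)
    out = np.column_stack([cent, result.von_mises_field])
    np.savetxt(path, out, delimiter=",", header="x_mm,y_mm,von_mises_pa", comments="")


def plot_vm(mesh: Mesh2D, result: FEResult, path, title: str = "") -> None:
    """Color-mapped von Mises field written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    tp = ax.tripcolor(
        mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles,
        facecolors=result.von_mises_field / 1e6, cmap="viridis",
    )
    fig.colorbar(tp, ax=ax, label="von Mises stress (MPa)")
    ax.set_aspect("equal")
    ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
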