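"""The two comparative loading scenarios and the mechanical-advantage metric.

Bending: the skull is fixed at the quadrates and a dorsally directed point
load is applied at the snout tip.  The reference load (100 N on the base
model) is scaled by planform area ratio so that pure size change does not
change the stress field — the comparison isolates proportions.

Biting: the quadrates are fixed, the bite point on the premaxilla is held
vertically to record the bite reaction, and the total adductor muscle force
— estimated dry-skull style as muscle specific tension times the area of the
upper-temporal opening — is distributed equally over the dorsal
temporal-margin nodes, each node pulling toward a posteroventral insertion
point.  Mechanical advantage is the vertical bite reaction divided by the
total muscle force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from morphomech.femesh import Mesh2D
from morphomech.fe_solver import BoundaryConditions
from morphomech.template import MIN_HOLE_FRACTION, Outline2D, hole_area

#: default muscle specific tension, N/mm^2 (0.3 MPa, a standard vertebrate
#: value; only relative comparisons matter as it is constant across models)
DEFAULT_MUSCLE_TENSION = 0.3


@dataclass(frozen=True)
class ScenarioSpec:
    """Loading-scenario parameters shared across a model sweep."""

    kind: str = "bending"               # {"bending", "biting"}
    F_ref: float = 100.0                # N, reference bending load
    A_ref: float | None = None          # mm^2, reference (base-model) area
    muscle_tension: float = DEFAULT_MUSCLE_TENSION   # N/mm^2
    muscle_insertion: tuple[float, float] | None = None  # mm; default (0.95L, -0.3H)

    def __post_init__(self):
        if self.kind not in ("bending", "biting"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.F_ref <= 0:
            raise ValueError("F_ref must be > 0")
        if self.muscle_tension <= 0:
            raise ValueError("muscle_tension must be > 0")


def scaled_load(F_ref: float, A_model: float, A_ref: float) -> float:
    """Area-corrected load: F_ref * (A_model / A_ref)."""
    if A_model <= 0 or A_ref <= 0:
        raise ValueError("areas must be > 0")
    return F_ref * A_model / A_ref


def bending_case(mesh: Mesh2D, spec: ScenarioSpec, A_model: float) -> BoundaryConditions:
    """Snout-tip bending: quadrates fixed, area-scaled dorsal tip load."""
    for req in ("snout_tip", "quadrate"):
        if req not in mesh.node_sets:
            raise KeyError(f"mesh lacks node set '{req}'")
    A_ref = spec.A_ref if spec.A_ref is not None else A_model
    F = scaled_load(spec.F_ref, A_model, A_ref)
    tip = int(mesh.node_sets["snout_tip"][0])
    return BoundaryConditions(
        fixed=[("quadrate", "xy")],
        point_loads=[(tip, (0.0, F))],
    )


def muscle_force(mesh: Mesh2D, outline: Outline2D, tension: float = DEFAULT_MUSCLE_TENSION) -> float:
    """Total adductor force (N): tension x upper-temporal opening area.

    The planar temporal opening is the 2-D proxy for the adductor chamber in
    dorsal view.
    """
    if "temporal" not in outline.holes:
        raise ValueError(
            "no upper-temporal opening: the biting scenario requires a braincase "
            f"fraction of at least {MIN_HOLE_FRACTION}"
        )
    if tension < 0:
        raise ValueError("tension must be >= 0")
    return tension * hole_area(outline, "temporal")


def biting_case(mesh: Mesh2D, outline: Outline2D, spec: ScenarioSpec) -> BoundaryConditions:
    """Muscle-driven biting boundary conditions.

    Quadrates fixed in both axes; bite node fixed in y only (its vertical
    reaction is the bite force); the total muscle force divided equally over
    the temporal-margin nodes, each nodal force directed as the unit vector
    from the node toward the muscle-insertion point.
    """
    for req in ("bite", "quadrate", "temporal_margin"):
        if req not in mesh.node_sets:
            raise KeyError(f"mesh lacks node set '{req}'")
    total = muscle_force(mesh, outline, spec.muscle_tension)
    margin = mesh.node_sets["temporal_margin"]
    insertion = spec.muscle_insertion
    if insertion is None:
        insertion = (0.95 * outline.length, -0.3 * outline.height)
    insertion = np.asarray(insertion, float)
    per_node = total / len(margin)
    vecs = insertion[None, :] - mesh.nodes[margin]
    norms = np.linalg.norm(vecs, axis=1)
    if (norms < 1e-12).any():
        raise ValueError("muscle insertion coincides with a margin node")
    forces = per_node * vecs / norms[:, None]
    return BoundaryConditions(
        fixed=[("quadrate", "xy"), ("bite", "y")],
        distributed_loads=[("temporal_margin", forces)],
    )


def mechanical_advantage(bite_reaction, total_muscle: float) -> float:
    """|vertical bite reaction| / total muscle force."""
    if total_muscle <= 0:
        raise ValueError("total_muscle must be > 0")
    ry = bite_reaction[1] if np.ndim(bite_reaction) else float(bite_reaction)
    return abs(float(ry)) / total_muscle
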