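"""Parametric 2-D lateral-view skull outlines.

A hypothetical skull is described by its ternary composition (rostrum,
orbital region, braincase fractions of length), its length-to-height ratio,
and its absolute length.  The template is a generalized, non-ornamented
archosauriform profile: a wedge-shaped snout rising from the tip to full
skull height, a level dorsal skull table, a domed braincase whose doming
grows with the braincase fraction (expanded braincases are deepened, not
merely lengthened), a dropping posterior margin, an elliptical orbit, an
elliptical upper-temporal opening (the jaw-adductor attachment site), and an
optional antorbital opening.  Opening widths are tied to each region's share
of the postrostral skull, so orbit-braincase exchange reshapes the openings
strongly while rostral elongation mostly translates them - the geometric
encoding of orbital liability alongside rostral stress-neutrality.

The plane-stress idealization carries an out-of-plane thickness
``t = thickness_coef * H`` so that homothetic scaling together with
area-corrected loads leaves the stress field invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from morphomech.morphometrics import TernaryCoord

# template constants (single configuration block); all heights in units of H,
# lengths in units of the relevant region length
SNOUT_TIP_TOP = 0.25        # dorsal margin height at the snout tip
FACIAL_RISE_X = 0.25        # fraction of L over which the dorsal margin reaches H
                            # for the base (60/20/20) model
FACIAL_RISE_SLOPE = 0.35    # partial coupling of the facial-rise span to the
                            # rostrum fraction: rise span = 0.25 + slope*(r - 0.6)
                            # of L. Full coupling (rise to rL) makes bending
                            # stress grow with rostral length; zero coupling
                            # makes it shrink (hole-load effects); partial
                            # coupling keeps rostral change stress-neutral
VENTRAL_TIP_RISE = 0.05     # ventral margin height at the snout tip
POSTERIOR_TOP = 0.85        # dorsal margin height at the quadrate
BRAINCASE_DOME = 0.90       # dorsal doming of the braincase: apex height
                            # H * (1 + BRAINCASE_DOME * b). An expanded
                            # braincase deepens the posterior skull (domed,
                            # inflated braincases) instead of merely widening
                            # its opening - the stiffening that makes
                            # expanded-braincase models resist bending
ORBIT_CENTER_Y = 0.55
# opening widths scale with each region's share of the postrostral skull
# (o/(o+b), b/(o+b)) times skull length: rostral elongation shifts the
# openings without resizing them (a long-snouted skull keeps a developed
# orbit), while orbit-braincase exchange reshapes them strongly
ORBIT_SEMI_X = 0.28         # x (o/(o+b)) x L
ORBIT_SEMI_Y = 0.25         # x H
TEMPORAL_CENTER_Y = 0.78
TEMPORAL_SEMI_X = 0.09      # x (b/(o+b)) x L
TEMPORAL_SEMI_Y = 0.12
ANTORBITAL_CENTER_X = 0.70  # x rostrum length
ANTORBITAL_SEMI = 0.15
HOLE_CLEARANCE = 0.05       # minimum gap to any other boundary, x H
MIN_HOLE_FRACTION = 0.08    # region fraction below which its hole is omitted
SNOUT_ANCHOR_Y = 0.15
BITE_X = 0.05               # bite point, x L
QUADRATE_TOP = 0.20         # quadrate segment upper bound, x H
THICKNESS_COEF = 0.30
ELLIPSE_SEGMENTS = 48


@dataclass(frozen=True)
class SkullParams:
    """Full parametric description of one hypothetical skull model."""

    tern: TernaryCoord
    ratio: float = 3.0
    length: float = 300.0  # mm
    with_antorbital: bool = False
    thickness_coef: float = THICKNESS_COEF

    def __post_init__(self):
        for name, v in (("r", self.tern.r), ("o", self.tern.o), ("b", self.tern.b)):
            if v < 0.05:
                raise ValueError(f"ternary component {name}={v} below the 0.05 template minimum")
        if not (0.4 <= self.ratio <= 6):
            raise ValueError(f"ratio {self.ratio} outside [0.4, 6]")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.thickness_coef <= 0:
            raise ValueError("thickness_coef must be > 0")

    @property
    def height(self) -> float:
        return self.length / self.ratio

    @property
    def thickness(self) -> float:
        """Out-of-plane thickness of the plane-stress model, mm."""
        return self.thickness_coef * self.height


@dataclass
class Outline2D:
    """Closed skull outline with holes and landmark anchors (mm coordinates)."""

    outer: np.ndarray                      # (n, 2), CCW, not closed
    holes: dict[str, np.ndarray] = field(default_factory=dict)  # CW each
    # anchors
    snout_tip: tuple[float, float] = (0.0, 0.0)
    bite_point: tuple[float, float] = (0.0, 0.0)
    quadrate_segment: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))
    temporal_margin: np.ndarray | None = None   # polyline on the dorsal temporal-hole boundary
    region_bounds: tuple[float, float] = (0.0, 0.0)  # x = r*L and x = (r+o)*L
    length: float = 0.0
    height: float = 0.0
    thickness: float = 0.0

    def polygon(self) -> Polygon:
        return Polygon(self.outer, [h for h in self.holes.values()])

    @classmethod
    def from_polygon(cls, outer, holes=None, thickness: float = 1.0) -> "Outline2D":
        """Wrap an arbitrary simple polygon (testing / generic geometries).

        Anchors default to the first outer vertex; the quadrate segment is
        degenerate and tags the nearest node only.
        """
        outer = np.asarray(outer, float)
        holes = {f"hole{i}": np.asarray(h, float) for i, h in enumerate(holes or [])}
        minx, miny = outer.min(axis=0)
        maxx, maxy = outer.max(axis=0)
        first = tuple(outer[0])
        return cls(
            outer=outer,
            holes=holes,
            snout_tip=first,
            bite_point=first,
            quadrate_segment=(first, first),
            length=maxx - minx,
            height=maxy - miny,
            thickness=thickness,
        )

    def to_wkt(self) -> str:
        return self.polygon().wkt

    def to_svg(self, path) -> None:
        """Write a standalone SVG of the outline for visual inspection."""
        poly = self.polygon()
        minx, miny, maxx, maxy = poly.bounds
        pad = 0.05 * max(maxx - minx, maxy - miny)

        def ring(coords):
            pts = " ".join(f"{x:.3f},{maxy + pad - (y - miny):.3f}" for x, y in coords)
            return f'<polygon points="{pts}" fill="none" stroke="black" stroke-width="{0.004 * (maxx - minx):.3f}"/>'

        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{minx - pad:.3f} {-pad:.3f} '
            f'{maxx - minx + 2 * pad:.3f} {maxy - miny + 2 * pad:.3f}">',
            ring(self.outer),
        ]
        parts += [ring(h) for h in self.holes.values()]
        parts.append("</svg>")
        with open(path, "w") as fh:
            fh.write("\n".join(parts))


def _ellipse(cx: float, cy: float, ax: float, ay: float, clockwise: bool = True) -> np.ndarray:
    """Ellipse polygon with vertices equally spaced by arc length.

    Uniform spacing matters downstream: hole rings become fixed mesh nodes,
    and uniform segments let the mesher grade its sizing field cleanly.
    """
    th_dense = np.linspace(0, 2 * np.pi, 2048)
    x, y = ax * np.cos(th_dense), ay * np.sin(th_dense)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    targets = np.linspace(0, arc[-1], ELLIPSE_SEGMENTS, endpoint=False)
    th = np.interp(targets, arc, th_dense)
    if clockwise:
        th = -th
    return np.column_stack([cx + ax * np.cos(th), cy + ay * np.sin(th)])


def _capped_ellipse(outer: Polygon, existing: list[np.ndarray], cx, cy, ax, ay, clearance, name):
    """Shrink an elliptical hole until it clears the outer boundary and other holes."""
    for scale in np.linspace(1.0, 0.05, 40):
        ring = _ellipse(cx, cy, ax * scale, ay * scale)
        hole = Polygon(ring)
        if not outer.contains(hole):
            continue
        if outer.exterior.distance(hole) < clearance:
            continue
        if any(Polygon(e).distance(hole) < clearance for e in existing):
            continue
        return ring
    raise ValueError(f"cannot place hole '{name}' with required clearance")


def build_outline(params: SkullParams) -> Outline2D:
    """Construct the template outline for one parameter set.

    Coordinate frame: x anteroposterior (0 = snout tip, L = quadrate),
    y dorsoventral (0 = ventral margin at the quadrate, dorsal positive).
    Deterministic and scale-equivariant: all coordinates are linear in L at
    fixed ratio and composition.
    """
    L, H = params.length, params.height
    r, o, b = params.tern.r, params.tern.o, params.tern.b
    x_ro = r * L           # rostrum/orbit boundary
    x_ob = (r + o) * L     # orbit/braincase boundary

    rise_frac = float(np.clip(FACIAL_RISE_X + FACIAL_RISE_SLOPE * (r - 0.6), 0.08, 0.6))
    x_rise = rise_frac * L                # facial slope reaches full height here
    x_table_end = max(x_ob, x_rise)       # skull table runs to the braincase dome
    apex_x = max(x_table_end + 1e-9 * L, (r + o + b / 2) * L)
    apex_y = H * (1 + BRAINCASE_DOME * b)
    dorsal = [(L, POSTERIOR_TOP * H), (apex_x, apex_y), (x_table_end, H)]
    if x_rise < x_table_end - 1e-9 * L:
        dorsal.append((x_rise, H))
    dorsal.append((0.0, SNOUT_TIP_TOP * H))
    outer = np.array(
        [
            (0.0, VENTRAL_TIP_RISE * H),   # snout tip, ventral
            (L, 0.0),                      # quadrate, ventral
            *dorsal,                       # posterior dorsal corner back to the tip
        ]
    )  # ventral left-to-right, then dorsal right-to-left: counter-clockwise
    outer_poly = Polygon(outer)
    if not outer_poly.exterior.is_ccw:  # pragma: no cover - orientation guard
        outer = outer[::-1]
        outer_poly = Polygon(outer)

    clearance = HOLE_CLEARANCE * min(H, L)
    postrostral = o + b
    holes: dict[str, np.ndarray] = {}
    placed: list[np.ndarray] = []
    if o >= MIN_HOLE_FRACTION:
        ring = _capped_ellipse(
            outer_poly, placed,
            (r + o / 2) * L, ORBIT_CENTER_Y * H,
            ORBIT_SEMI_X * (o / postrostral) * L, ORBIT_SEMI_Y * H,
            clearance, "orbit",
        )
        holes["orbit"] = ring
        placed.append(ring)
    if b >= MIN_HOLE_FRACTION:
        ring = _capped_ellipse(
            outer_poly, placed,
            (r + o + b / 2) * L, TEMPORAL_CENTER_Y * H,
            TEMPORAL_SEMI_X * (b / postrostral) * L, TEMPORAL_SEMI_Y * H,
            clearance, "temporal",
        )
        holes["temporal"] = ring
        placed.append(ring)
    if params.with_antorbital and r >= 0.3:
        ring = _capped_ellipse(
            outer_poly, placed,
            ANTORBITAL_CENTER_X * r * L, ORBIT_CENTER_Y * H,
            ANTORBITAL_SEMI * r * L, ANTORBITAL_SEMI * r * L,
            clearance, "antorbital",
        )
        holes["antorbital"] = ring
        placed.append(ring)

    # ventral margin runs (0, 0.05H) -> (L, 0); bite point sits on it
    bite_y = VENTRAL_TIP_RISE * H * (1 - BITE_X)
    temporal_margin = None
    if "temporal" in holes:
        ring = holes["temporal"]
        cy = TEMPORAL_CENTER_Y * H
        dorsal = ring[ring[:, 1] >= cy - 1e-12]
        temporal_margin = dorsal[np.argsort(dorsal[:, 0])]

    return Outline2D(
        outer=outer,
        holes=holes,
        snout_tip=(0.0, SNOUT_ANCHOR_Y * H),
        bite_point=(BITE_X * L, bite_y),
        quadrate_segment=((L, 0.0), (L, QUADRATE_TOP * H)),
        temporal_margin=temporal_margin,
        region_bounds=(x_ro, x_ob),
        length=L,
        height=H,
        thickness=params.thickness,
    )


def _shoelace(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def outline_area(outline: Outline2D) -> float:
    """Net planform area (mm^2): outer area minus hole areas (shoelace)."""
    area = _shoelace(outline.outer)
    for h in outline.holes.values():
        area -= _shoelace(h)
    return area


def gross_area(outline: Outline2D) -> float:
    """Envelope planform area (mm^2), holes not subtracted.

    The 2-D proxy for skull surface area in the load correction: openings
    barely reduce the outer surface of a real skull.
    """
    return _shoelace(outline.outer)


def hole_area(outline: Outline2D, name: str) -> float:
    if name not in outline.holes:
        raise KeyError(f"outline has no hole '{name}'")
    return _shoelace(outline.holes[name])
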