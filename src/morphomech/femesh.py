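"""Quality triangulation of skull outlines with tagged boundary node sets.

The mesher follows the classic force-equilibrium ("DistMesh") idea: boundary
rings are resampled at the target element size and held fixed, interior
points start on a hexagonal lattice and relax under linear repulsive bar
forces, with the triangulation recomputed from the Delaunay of the current
point set and triangles outside the material (outside the outer ring or
inside a hole) discarded by a centroid point-in-polygon test.  Because every
boundary node lies exactly on the outline polygon and boundary spacing is
kept below the hole-clearance feature size, the triangulated region
reproduces the polygon exactly and total element area matches the outline
area to round-off.

Everything is deterministic for a fixed outline and target size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from morphomech.template import TEMPORAL_CENTER_Y, Outline2D, outline_area

DEFAULT_H_FACTOR = 60  # default target_h = L / 60


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2-D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh2D:
    """Planar triangle mesh with named boundary node sets (mm coordinates)."""

    nodes: np.ndarray                   # (n, 2) mm
    triangles: np.ndarray               # (m, 3) int, counter-clockwise
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    target_h: float = 0.0
    thickness: float = 0.0              # out-of-plane thickness, mm

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def min_angle_deg(self) -> float:
        p = self.nodes[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    def to_csv(self, node_path, element_path) -> None:
        np.savetxt(node_path, self.nodes, delimiter=",", header="x_mm,y_mm", comments="")
        np.savetxt(element_path, self.triangles, fmt="%d", delimiter=",", header="n1,n2,n3", comments="")

    def to_gmsh(self, path) -> None:
        """Write Gmsh ASCII v2 for external inspection."""
        lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(self.n_nodes)]
        lines += [f"{i + 1} {x:.9g} {y:.9g} 0" for i, (x, y) in enumerate(self.nodes)]
        lines += ["$EndNodes", "$Elements", str(self.n_elements)]
        lines += [
            f"{i + 1} 2 2 0 1 {t[0] + 1} {t[1] + 1} {t[2] + 1}"
            for i, t in enumerate(self.triangles)
        ]
        lines += ["$EndElements"]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _resample_ring(ring: np.ndarray, sizing, anchors: list[np.ndarray] | None = None) -> np.ndarray:
    """Resample a closed polyline at the local target size, keeping vertices.

    ``sizing`` maps (n, 2) points to local target edge lengths; segments are
    split recursively until each is no longer than the size at its midpoint.
    ``anchors`` are extra points (must lie on the ring) inserted as vertices
    first so they survive resampling exactly.
    """
    pts = [np.asarray(p, float) for p in ring]
    scale = float(sizing(np.asarray(ring)).min())
    if anchors:
        for a in anchors:
            a = np.asarray(a, float)
            if min(np.linalg.norm(np.array(pts) - a, axis=1)) < 1e-9:
                continue
            # insert on the nearest segment
            best, best_d = None, np.inf
            for i in range(len(pts)):
                p, q = pts[i], pts[(i + 1) % len(pts)]
                seg = q - p
                t = np.clip(np.dot(a - p, seg) / np.dot(seg, seg), 0, 1)
                d = np.linalg.norm(p + t * seg - a)
                if d < best_d:
                    best, best_d = i, d
            if best_d > 1e-6 * scale + 1e-9:
                raise MeshingError(f"anchor {a} not on ring (distance {best_d:.3g})")
            pts.insert(best + 1, a)

    def subdivide(p, q):
        seglen = np.linalg.norm(q - p)
        h_loc = float(sizing(((p + q) / 2)[None, :])[0])
        if seglen <= h_loc * (1 + 1e-9):
            return [p]
        mid = (p + q) / 2
        return subdivide(p, mid) + subdivide(mid, q)

    out = []
    n = len(pts)
    for i in range(n):
        out.extend(subdivide(pts[i], pts[(i + 1) % n]))
    return np.array(out)


def _signed_distance(poly: Polygon, pts: np.ndarray) -> np.ndarray:
    """Negative inside the material, positive outside."""
    d = shapely.distance(shapely.points(pts), poly.boundary)
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return np.where(inside, -d, d)


def _good_triangles(poly: Polygon, nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    cent = nodes[tris].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    p = nodes[tris]
    areas = np.abs(0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    # drop exactly-degenerate slivers from collinear boundary points
    keep &= areas > 1e-12 * max(poly.area, 1e-300)
    return tris[keep]


def _sizing_field(outline: Outline2D, h0: float):
    """Local target edge length: h0 away from features, finer near holes.

    Each hole's local size is its clearance to the rest of the boundary
    (capped at h0), graded back to h0 at 35% per unit distance, so narrow
    necks between a hole and the outer margin are resolved by elements that
    fit through them.  The field is scale-equivariant: all ingredients are
    lengths.  Returns (callable, minimum size).
    """
    if not outline.holes:
        return (lambda pts: np.full(len(np.atleast_2d(pts)), h0)), h0

    from shapely.geometry import LinearRing

    outer_ring = LinearRing(outline.outer)
    hole_geoms = {name: LinearRing(ring) for name, ring in outline.holes.items()}
    fine: dict[str, float] = {}
    for name, geom in hole_geoms.items():
        clearance = geom.distance(outer_ring)
        for other, og in hole_geoms.items():
            if other != name:
                clearance = min(clearance, geom.distance(og))
        # local size must match the ring's (uniform) segment length exactly:
        # ring nodes are fixed, and resampling subdivides segments by halving,
        # so the effective size is the segment length after k halvings
        ring = outline.holes[name]
        seg = np.linalg.norm(np.diff(np.vstack([ring, ring[:1]]), axis=0), axis=1)
        s = float(seg.max())
        target = min(h0, clearance)
        if s <= target:
            fine[name] = s
        else:
            k = int(np.ceil(np.log2(s / target) - 1e-12))
            fine[name] = s / 2**k
    h_min = min(fine.values())

    def sizing(pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        geoms = shapely.points(pts)
        h = np.full(len(pts), h0)
        for name, geom in hole_geoms.items():
            d = shapely.distance(geoms, geom)
            h = np.minimum(h, fine[name] + 0.35 * d)
        return h

    return sizing, h_min


MIN_ANGLE_DEG = 20.0


def _tri_min_angles(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    angs = []
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1), 1e-300
        )
        angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return np.min(angs, axis=0)


def _circumcenters(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    d = 2 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1]) + c[:, 0] * (a[:, 1] - b[:, 1]))
    d = np.where(np.abs(d) < 1e-300, 1e-300, d)
    a2 = (a**2).sum(axis=1)
    b2 = (b**2).sum(axis=1)
    c2 = (c**2).sum(axis=1)
    ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
    uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
    return np.column_stack([ux, uy])


def _polish(poly: Polygon, points: np.ndarray, n_fixed: int, sizing):
    """Laplacian smoothing plus sliver-node removal until angles clear 20 deg."""
    for rnd in range(15):
        tri = Delaunay(points)
        tris = _good_triangles(poly, points, tri.simplices)
        mina = _tri_min_angles(points, tris)
        if mina.min() >= MIN_ANGLE_DEG:
            break
        if rnd >= 2:
            # slivers whose three nodes are all fixed boundary nodes can only
            # be fixed by inserting a Steiner point (circumcenter, Ruppert-style)
            allfixed = tris[(mina < MIN_ANGLE_DEG) & (tris < n_fixed).all(axis=1)]
            if len(allfixed):
                p0, p1, p2 = (points[allfixed[:, i]] for i in range(3))
                cc = _circumcenters(p0, p1, p2)
                dcc = _signed_distance(poly, cc)
                ok = dcc < -0.4 * sizing(cc)
                if ok.any():
                    points = np.vstack([points, cc[ok]])
                    continue
        if rnd >= 4 and rnd % 2 == 0:
            # delete interior nodes in persistent slivers, but only when they
            # crowd another node (deleting sparse nodes would open cavities)
            bad_nodes = np.unique(tris[mina < MIN_ANGLE_DEG])
            bad_nodes = bad_nodes[bad_nodes >= n_fixed]
            if len(bad_nodes):
                from scipy.spatial import cKDTree

                tree = cKDTree(points)
                nn, _ = tree.query(points[bad_nodes], k=2)
                h_loc = sizing(points[bad_nodes])
                crowded = bad_nodes[nn[:, 1] < 0.6 * h_loc]
                if len(crowded):
                    keep = np.ones(len(points), bool)
                    keep[crowded] = False
                    points = points[keep]
                    continue
        # Laplacian sweep on interior nodes
        edges = np.unique(
            np.sort(np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1),
            axis=0,
        )
        acc = np.zeros_like(points)
        cnt = np.zeros(len(points))
        np.add.at(acc, edges[:, 0], points[edges[:, 1]])
        np.add.at(acc, edges[:, 1], points[edges[:, 0]])
        np.add.at(cnt, edges[:, 0], 1)
        np.add.at(cnt, edges[:, 1], 1)
        new = acc / np.maximum(cnt, 1)[:, None]
        new[:n_fixed] = points[:n_fixed]
        new[cnt == 0] = points[cnt == 0]
        # keep smoothed nodes inside the material
        d = _signed_distance(poly, new[n_fixed:])
        h_loc = sizing(new[n_fixed:])
        escaped = d > -0.2 * h_loc
        new[n_fixed:][escaped] = points[n_fixed:][escaped]
        points = new

    tri = Delaunay(points)
    tris = _good_triangles(poly, points, tri.simplices)
    return points, tris


def triangulate(outline: Outline2D, target_h: float | None = None, max_iter: int = 80) -> Mesh2D:
    """Triangulate an outline into a quality mesh with tagged node sets.

    Node sets: ``snout_tip`` and ``bite`` (single nearest boundary node
    each), ``quadrate`` (all boundary nodes on the posterior quadrate
    segment), ``temporal_margin`` (all nodes on the dorsal half of the
    upper-temporal opening, when present).
    """
    L = outline.length
    if target_h is None:
        target_h = L / DEFAULT_H_FACTOR
    is_skull = np.linalg.norm(
        np.asarray(outline.quadrate_segment[1]) - np.asarray(outline.quadrate_segment[0])
    ) > 1e-12
    if is_skull and target_h > L / 20:
        raise ValueError(f"target_h={target_h} too coarse (must be <= L/20)")
    if target_h > L / 2:
        raise ValueError(f"target_h={target_h} too coarse for outline of extent {L}")
    poly = outline.polygon()
    sizing, h_min = _sizing_field(outline, target_h)

    anchors = [
        np.array(outline.snout_tip),
        np.array(outline.bite_point),
        np.array(outline.quadrate_segment[0]),
        np.array(outline.quadrate_segment[1]),
    ]
    rings = [("outer", _resample_ring(outline.outer, sizing, anchors))]
    for name, ring in outline.holes.items():
        rings.append((name, _resample_ring(ring, sizing)))
    fixed = np.vstack([r for _, r in rings])
    ring_of = np.concatenate([[i] * len(r) for i, (_, r) in enumerate(rings)])
    n_fixed = len(fixed)

    # hexagonal lattice at the finest size, thinned by the sizing field with
    # a deterministic scale-free quasi-random keep rule, clear of the boundary
    xmin, ymin, xmax, ymax = poly.bounds
    ref = max(xmax - xmin, ymax - ymin)
    xs = xmin + np.arange(0, (xmax - xmin) / h_min + 1) * h_min
    ys = ymin + np.arange(0, (ymax - ymin) / (h_min * np.sqrt(3) / 2) + 1) * (h_min * np.sqrt(3) / 2)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += h_min / 2
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    h_at = sizing(pts)
    keep_prob = (h_min / h_at) ** 2
    u = np.modf(np.abs(np.sin((pts[:, 0] / ref) * 12.9898 + (pts[:, 1] / ref) * 78.233) * 43758.5453))[0]
    pts = pts[u < keep_prob]
    d = _signed_distance(poly, pts)
    interior = pts[d < -0.6 * sizing(pts)]

    points = np.vstack([fixed, interior])
    Fscale, dt = 1.2, 0.2
    last = points.copy() + 10 * h_min
    edges = None
    for _ in range(max_iter):
        if np.max(np.linalg.norm(points - last, axis=1)) > 0.08 * h_min:
            last = points.copy()
            tri = Delaunay(points)
            keep = _good_triangles(poly, points, tri.simplices)
            edges = np.unique(
                np.sort(
                    np.vstack([keep[:, [0, 1]], keep[:, [1, 2]], keep[:, [2, 0]]]), axis=1
                ),
                axis=0,
            )
        vec = points[edges[:, 0]] - points[edges[:, 1]]
        lens = np.linalg.norm(vec, axis=1)
        hbars = sizing((points[edges[:, 0]] + points[edges[:, 1]]) / 2)
        L0 = hbars * Fscale * np.sqrt((lens**2).sum() / (hbars**2).sum())
        force = np.maximum(L0 - lens, 0)
        fvec = vec / np.maximum(lens, 1e-12)[:, None] * force[:, None]
        move = np.zeros_like(points)
        np.add.at(move, edges[:, 0], fvec)
        np.add.at(move, edges[:, 1], -fvec)
        move[:n_fixed] = 0
        points = points + dt * move
        # pull escaped interior points back inside
        h_loc = sizing(points[n_fixed:])
        dmov = _signed_distance(poly, points[n_fixed:])
        out = dmov > -0.2 * h_loc
        if out.any():
            esc = points[n_fixed:][out]
            eps = 1e-6 * h_min
            d0 = _signed_distance(poly, esc)
            dx = (_signed_distance(poly, esc + [eps, 0]) - d0) / eps
            dy = (_signed_distance(poly, esc + [0, eps]) - d0) / eps
            grad = np.column_stack([dx, dy])
            grad /= np.maximum(np.linalg.norm(grad, axis=1), 1e-12)[:, None]
            points[n_fixed:][out] = esc - (d0 + 0.45 * h_loc[out])[:, None] * grad
        interior_move = np.linalg.norm(dt * move[n_fixed:], axis=1) if len(points) > n_fixed else np.array([0.0])
        if interior_move.size and interior_move.max() < 0.002 * h_min:
            break

    # drop relaxed interior points that ended up crowding the fixed boundary
    if len(points) > n_fixed:
        dfin = _signed_distance(poly, points[n_fixed:])
        keep_int = dfin < -0.45 * sizing(points[n_fixed:])
        points = np.vstack([fixed, points[n_fixed:][keep_int]])

    points, tris = _polish(poly, points, n_fixed, sizing)
    # enforce counter-clockwise orientation
    p = points[tris]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = areas < 0
    tris[flip] = tris[flip][:, ::-1]

    mesh = Mesh2D(
        nodes=points,
        triangles=tris,
        target_h=target_h,
        thickness=outline.thickness,
    )
    mesh.node_sets = _tag_node_sets(mesh, outline, rings, ring_of, n_fixed)

    total = mesh.element_areas().sum()
    ref = outline_area(outline)
    if abs(total - ref) > 1e-6 * ref:
        raise MeshingError(
            f"mesh area {total:.6g} deviates from outline area {ref:.6g}; boundary not recovered"
        )
    return mesh


def _tag_node_sets(mesh, outline, rings, ring_of, n_fixed) -> dict[str, np.ndarray]:
    nodes = mesh.nodes
    sets: dict[str, np.ndarray] = {}

    def nearest(point) -> np.ndarray:
        return np.array([int(np.argmin(np.linalg.norm(nodes[:n_fixed] - point, axis=1)))])

    sets["snout_tip"] = nearest(np.array(outline.snout_tip))
    sets["bite"] = nearest(np.array(outline.bite_point))

    (qa, qb) = outline.quadrate_segment
    qa, qb = np.array(qa), np.array(qb)
    if np.linalg.norm(qb - qa) < 1e-12:
        sets["quadrate"] = nearest(qa)
    else:
        on_seg = []
        seg = qb - qa
        for i in range(n_fixed):
            p = nodes[i]
            t = np.dot(p - qa, seg) / np.dot(seg, seg)
            if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(qa + np.clip(t, 0, 1) * seg - p) < 1e-6 * outline.length:
                on_seg.append(i)
        sets["quadrate"] = np.array(sorted(on_seg))
        if len(sets["quadrate"]) < 2:
            raise MeshingError("quadrate set needs >= 2 nodes")

    temporal_idx = None
    for k, (name, _) in enumerate(rings):
        if name == "temporal":
            temporal_idx = k
    if temporal_idx is not None:
        cy = TEMPORAL_CENTER_Y * outline.height
        members = [
            i for i in range(n_fixed)
            if ring_of[i] == temporal_idx and nodes[i, 1] >= cy - 1e-9
        ]
        sets["temporal_margin"] = np.array(sorted(members))

    for name, idx in sets.items():
        if len(idx) == 0:
            raise MeshingError(f"node set '{name}' is empty")
    return sets
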