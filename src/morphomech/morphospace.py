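"""Ternary-simplex geometry, the theoretical model grid, and performance surfaces.

The theoretical morphospace is the set of (rostrum, orbit, braincase)
compositions on a fixed-step lattice with every component above a viability
minimum (a region below 10% of skull length is treated as anatomically
impossible).  Each lattice point is one hypothetical skull model; solving
both loading scenarios at every point yields a performance surface that can
be interpolated at arbitrary compositions, e.g. at measured species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from morphomech.morphometrics import SpeciesRecord, TernaryCoord, proportions

SIMPLEX_AREA = np.sqrt(3) / 4  # area of the full ternary triangle in plot coordinates


@dataclass
class TernaryGrid:
    """Lattice of viable compositions at a given step."""

    step: float
    min_component: float
    points: list[TernaryCoord]

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.array([[p.r, p.o, p.b] for p in self.points])


def enumerate_grid(step: float = 0.10, min_component: float = 0.10) -> TernaryGrid:
    """All compositions on the step lattice with each component >= minimum.

    Sorted lexicographically by descending rostrum then descending orbit.
    The count equals the number of integer compositions of ``1/step`` into
    three parts each >= ``min_component/step``.
    """
    if not (0 < step <= min_component <= 1 / 3 + 1e-12):
        raise ValueError("require 0 < step <= min_component <= 1/3")
    n = round(1 / step)
    kmin = round(min_component / step)
    pts = []
    for i in range(n, -1, -1):          # rostrum descending
        for j in range(n - i, -1, -1):  # orbit descending
            k = n - i - j
            if i >= kmin and j >= kmin and k >= kmin:
                pts.append(TernaryCoord(i / n, j / n, k / n))
    return TernaryGrid(step=step, min_component=min_component, points=pts)


def ternary_to_cartesian(coord: TernaryCoord | np.ndarray) -> np.ndarray:
    """Standard ternary plot mapping.

    Corners: pure rostrum -> (0, 0); pure orbit -> (1, 0); pure braincase
    -> (0.5, sqrt(3)/2).  Affine in the composition.
    """
    if isinstance(coord, TernaryCoord):
        arr = coord.as_array()[None, :]
        single = True
    else:
        arr = np.atleast_2d(np.asarray(coord, float))
        single = arr.shape[0] == 1 and np.ndim(coord) == 1
    x = arr[:, 1] + arr[:, 2] / 2
    y = arr[:, 2] * np.sqrt(3) / 2
    out = np.column_stack([x, y])
    return out[0] if single else out


def occupancy_fraction(coords: list[TernaryCoord] | np.ndarray) -> float:
    """Convex-hull area of the points divided by the full simplex area.

    Returns 0 for fewer than three points or a collinear set.
    """
    if isinstance(coords, np.ndarray):
        arr = coords
    else:
        arr = np.array([[c.r, c.o, c.b] for c in coords])
    if len(arr) < 3:
        return 0.0
    xy = ternary_to_cartesian(arr)
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return 0.0
    return float(hull.volume / SIMPLEX_AREA)  # 2-D "volume" is the area


def alpha_occupancy_fraction(coords, alpha: float) -> float:
    """Alpha-shape occupancy: union of Delaunay triangles with
    circumradius <= 1/alpha, as a fraction of the simplex area."""
    arr = coords if isinstance(coords, np.ndarray) else np.array([[c.r, c.o, c.b] for c in coords])
    if len(arr) < 3:
        return 0.0
    xy = ternary_to_cartesian(arr)
    try:
        tri = Delaunay(xy)
    except QhullError:
        return 0.0
    area = 0.0
    for simplex in tri.simplices:
        a, b, c = xy[simplex]
        la, lb, lc = np.linalg.norm(b - c), np.linalg.norm(c - a), np.linalg.norm(a - b)
        t_area = 0.5 * abs((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0])
        if t_area < 1e-15:
            continue
        circum_r = la * lb * lc / (4 * t_area)
        if circum_r <= 1 / alpha:
            area += t_area
    return float(area / SIMPLEX_AREA)


@dataclass
class PerformanceSurface:
    """Per-grid-point biomechanical metrics."""

    grid: TernaryGrid
    bending_median_vm: np.ndarray       # Pa
    biting_median_vm: np.ndarray        # Pa
    mechanical_advantage: np.ndarray    # dimensionless
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.grid)
        for name in ("bending_median_vm", "biting_median_vm", "mechanical_advantage"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per grid point")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{name} must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        arr = self.grid.as_array()
        return pd.DataFrame(
            {
                "rostrum": arr[:, 0],
                "orbit": arr[:, 1],
                "braincase": arr[:, 2],
                "bending_median_vm_pa": self.bending_median_vm,
                "biting_median_vm_pa": self.biting_median_vm,
                "mechanical_advantage": self.mechanical_advantage,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def metric_names(self):
        return ("bending_median_vm", "biting_median_vm", "mechanical_advantage")


@dataclass
class RatioSeries:
    """Metrics along the length-to-height ratio axis at fixed composition."""

    ratios: np.ndarray
    bending_median_vm: np.ndarray
    biting_median_vm: np.ndarray
    mechanical_advantage: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.ratios, float)
        if (np.diff(r) <= 0).any() or (r <= 0).any():
            raise ValueError("ratios must be strictly increasing and positive")
        self.ratios = r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": self.ratios,
                "bending_median_vm_pa": self.bending_median_vm,
                "biting_median_vm_pa": self.biting_median_vm,
                "mechanical_advantage": self.mechanical_advantage,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_RATIOS = np.arange(0.5, 5.01, 0.5)


def interpolate_surface(surface: PerformanceSurface, query: TernaryCoord):
    """Barycentric-linear interpolation of all three metrics at a composition.

    Queries outside the convex hull of the grid fall back to the nearest
    grid point and are flagged.  Returns (values dict, extrapolated flag).
    """
    if len(surface.grid) == 0:
        raise ValueError("empty surface")
    xy = ternary_to_cartesian(surface.grid.as_array())
    q = ternary_to_cartesian(query)
    tri = Delaunay(xy)
    simplex = tri.find_simplex(q[None, :])
    values = {}
    if simplex[0] >= 0:
        s = tri.simplices[simplex[0]]
        T = tri.transform[simplex[0]]
        bary2 = T[:2] @ (q - T[2])
        bary = np.append(bary2, 1 - bary2.sum())
        for name in surface.metric_names:
            values[name] = float(np.dot(bary, getattr(surface, name)[s]))
        return values, False
    nearest = int(np.argmin(np.linalg.norm(xy - q, axis=1)))
    for name in surface.metric_names:
        values[name] = float(getattr(surface, name)[nearest])
    return values, True


def species_performance(records: list[SpeciesRecord], surface: PerformanceSurface) -> pd.DataFrame:
    """Interpolated metrics and grid-relative percentiles per species.

    Percentiles are the percentage of grid models with a metric value below
    the species' interpolated value.
    """
    rows = []
    grid_vals = {name: np.asarray(getattr(surface, name)) for name in surface.metric_names}
    for rec in records:
        tern = proportions(rec)
        values, extrapolated = interpolate_surface(surface, tern)
        row = {
            "species": rec.species_name,
            "clade": rec.clade,
            "rostrum": tern.r,
            "orbit": tern.o,
            "braincase": tern.b,
            "extrapolated": extrapolated,
        }
        for name in surface.metric_names:
            v = values[name]
            row[name] = v
            row[f"{name}_percentile"] = 100.0 * float(np.mean(grid_vals[name] < v))
        rows.append(row)
    return pd.DataFrame(rows)
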