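import itertools

import numpy as np
import pytest

from morphomech import morphospace as MS
from morphomech.morphometrics import SpeciesRecord, TernaryCoord
from morphomech.morphospace import (
    PerformanceSurface,
    enumerate_grid,
    interpolate_surface,
    occupancy_fraction,
    species_performance,
    ternary_to_cartesian,
)


def brute_force_count(step, minimum):
    """Independent enumeration of lattice compositions by exhaustive search."""
    n = round(1 / step)
    k = round(minimum / step)
    return sum(
        1
        for i, j in itertools.product(range(n + 1), repeat=2)
        if i >= k and j >= k and (n - i - j) >= k
    )


class TestEnumerateGrid:
    @pytest.mark.parametrize("step, minimum", [(0.10, 0.10), (0.20, 0.20), (0.10, 0.20), (0.05, 0.10)])
    def test_count_matches_brute_force(self, step, minimum):
        grid = enumerate_grid(step, minimum)
        assert len(grid) == brute_force_count(step, minimum)

    def test_default_grid_has_36_models(self):
        assert len(enumerate_grid()) == 36

    def test_coarse_grid_has_6_models(self):
        assert len(enumerate_grid(0.20, 0.20)) == 6

    def test_base_composition_is_a_member(self):
        pts = enumerate_grid().points
        assert any(
            (p.r, p.o, p.b) == pytest.approx((0.6, 0.2, 0.2), abs=1e-12) for p in pts
        )

    def test_points_unique_and_on_lattice(self):
        grid = enumerate_grid()
        arr = grid.as_array()
        assert len(np.unique(arr.round(12), axis=0)) == len(arr)
        assert np.allclose(arr / grid.step, np.round(arr / grid.step), atol=1e-9)
        assert (arr >= grid.min_component - 1e-12).all()

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid(0.2, 0.1)


class TestTernaryToCartesian:
    @pytest.mark.parametrize(
        "comp, expected",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (1.0, 0.0)),
            ((0, 0, 1), (0.5, np.sqrt(3) / 2)),
            ((1 / 3, 1 / 3, 1 / 3), (0.5, np.sqrt(3) / 6)),
            ((0.6, 0.2, 0.2), (0.3, 0.1 * np.sqrt(3))),
        ],
    )
    def test_known_points(self, comp, expected):
        xy = ternary_to_cartesian(np.asarray(comp, float))
        assert xy == pytest.approx(expected)

    def test_affine_in_composition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b = rng.dirichlet([1, 1, 1]), rng.dirichlet([1, 1, 1])
            t = rng.uniform()
            lhs = ternary_to_cartesian(t * a + (1 - t) * b)
            rhs = t * ternary_to_cartesian(a) + (1 - t) * ternary_to_cartesian(b)
            assert np.allclose(lhs, rhs)


class TestOccupancy:
    def test_full_simplex_corners(self):
        eps = 1e-12
        corners = np.array([[1 - 2 * eps, eps, eps], [eps, 1 - 2 * eps, eps], [eps, eps, 1 - 2 * eps]])
        assert occupancy_fraction(corners) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_sets_are_zero(self):
        assert occupancy_fraction(np.array([[0.4, 0.3, 0.3]])) == 0.0
        collinear = np.array([[0.2 + 0.1 * i, 0.4, 0.4 - 0.1 * i] for i in range(4)])
        assert occupancy_fraction(collinear) == 0.0

    def test_permutation_and_interior_point_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.dirichlet([2, 2, 2], size=30)
        base = occupancy_fraction(pts)
        assert occupancy_fraction(pts[::-1]) == pytest.approx(base)
        centroid = pts.mean(axis=0, keepdims=True)
        assert occupancy_fraction(np.vstack([pts, centroid])) == pytest.approx(base)

    def test_alpha_occupancy_below_hull(self):
        rng = np.random.default_rng(6)
        pts = rng.dirichlet([2, 2, 2], size=60)
        hull = occupancy_fraction(pts)
        alpha = MS.alpha_occupancy_fraction(pts, alpha=8.0)
        assert 0.0 <= alpha <= hull + 1e-9


def _toy_surface():
    grid = enumerate_grid()
    arr = grid.as_array()
    # affine metric fields: linear interpolation must be exact
    bend = 1.0 + 2.0 * arr[:, 0] + 3.0 * arr[:, 1]
    bite = 0.5 + arr[:, 2]
    ma = 0.1 + 0.2 * arr[:, 2]
    return PerformanceSurface(grid, bend, bite, ma)


class TestInterpolateSurface:
    def test_identity_at_grid_points(self):
        surf = _toy_surface()
        for idx in (0, 7, 35):
            vals, flagged = interpolate_surface(surf, surf.grid.points[idx])
            assert not flagged
            assert vals["bending_median_vm"] == pytest.approx(surf.bending_median_vm[idx])

    def test_linear_field_reproduced_anywhere_inside(self):
        surf = _toy_surface()
        q = TernaryCoord(0.47, 0.26, 0.27)
        vals, flagged = interpolate_surface(surf, q)
        assert not flagged
        assert vals["bending_median_vm"] == pytest.approx(1.0 + 2.0 * 0.47 + 3.0 * 0.26)

    def test_outside_hull_flags_extrapolation(self):
        surf = _toy_surface()
        vals, flagged = interpolate_surface(surf, TernaryCoord(0.96, 0.02, 0.02))
        assert flagged
        # nearest grid point is the rostrum-most composition (0.8, 0.1, 0.1)
        assert vals["bending_median_vm"] == pytest.approx(1.0 + 2.0 * 0.8 + 3.0 * 0.1)

    def test_monotone_transect_preserved(self):
        surf = _toy_surface()
        queries = [TernaryCoord(0.6 - t, 0.2, 0.2 + t) for t in np.linspace(0, 0.2, 9)]
        vals = [interpolate_surface(surf, q)[0]["biting_median_vm"] for q in queries]
        assert all(b > a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSpeciesPerformance:
    def test_species_at_base_composition_gets_base_metrics(self):
        surf = _toy_surface()
        rec = SpeciesRecord("Basal_forma", "other", "other/unknown", "Triassic", 310, 180, 60, 60, 100)
        table = species_performance([rec], surf)
        idx = [i for i, p in enumerate(surf.grid.points) if abs(p.r - 0.6) < 1e-9 and abs(p.o - 0.2) < 1e-9]
        assert table.loc[0, "bending_median_vm"] == pytest.approx(surf.bending_median_vm[idx[0]])
        assert not table.loc[0, "extrapolated"]

    def test_percentiles_below_100_off_extremes(self):
        surf = _toy_surface()
        rec = SpeciesRecord("Mid_forma", "other", "other/unknown", "Triassic", 310, 120, 90, 90, 100)
        table = species_performance([rec], surf)
        for col in table.columns:
            if col.endswith("_percentile"):
                assert 0.0 <= table.loc[0, col] < 100.0
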