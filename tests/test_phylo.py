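import numpy as np
import pytest
from scipy.optimize import minimize

from morphomech import phylo
from morphomech.morphometrics import SpeciesRecord
from morphomech.phylo import ancestral_states, read_newick, sq_change_objective, write_newick


class TestNewickIO:
    def test_cherry_parses(self):
        pt = read_newick("(A:1,B:1):0;")
        assert sorted(pt.tip_labels()) == ["A", "B"]

    def test_round_trip_idempotent(self):
        text = "((A:1.5,B:2.25):0.5,C:3.0):0.0;"
        once = write_newick(read_newick(text))
        twice = write_newick(read_newick(once))
        assert once == twice

    def test_unmatched_parenthesis_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((A:1,B:1:0;")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError):
            read_newick("(A:1,B):0;")

    def test_nonpositive_branch_length_rejected(self):
        with pytest.raises(ValueError):
            read_newick("(A:1,B:-2):0;")


def brute_force_states(ptree, tip_values, x0, seed=0):
    """Direct numerical minimization of the weighted squared-change objective."""
    internal = [n for n in ptree.tree.preorder_node_iter() if not n.is_leaf()]
    base = {n: np.asarray(v, float) for n, v in zip(internal, x0)}
    for leaf in ptree.tree.leaf_node_iter():
        base[leaf] = np.asarray(tip_values[leaf.taxon.label], float)

    def fun(x):
        st = dict(base)
        for i, n in enumerate(internal):
            st[n] = x[2 * i : 2 * i + 2]
        return sq_change_objective(ptree, st)

    rng = np.random.default_rng(seed)
    start = np.concatenate([base[n] for n in internal]) + rng.normal(scale=0.3, size=2 * len(internal))
    res = minimize(fun, start, method="BFGS", options={"gtol": 1e-12})
    return res.fun


class TestAncestralStates:
    def test_cherry_equal_branches_averages(self):
        pt = read_newick("(A:1,B:1):0;")
        st = ancestral_states(pt, {"A": np.array([0.0, 0.0]), "B": np.array([1.0, 2.0])})
        assert st[pt.tree.seed_node] == pytest.approx([0.5, 1.0])

    def test_star_tree_root_at_centroid(self):
        pt = read_newick("(A:1,B:1,C:1):0;")
        corners = {
            "A": np.array([0.0, 0.0]),
            "B": np.array([1.0, 0.0]),
            "C": np.array([0.5, np.sqrt(3) / 2]),
        }
        st = ancestral_states(pt, corners)
        assert st[pt.tree.seed_node] == pytest.approx([0.5, np.sqrt(3) / 6])

    def test_tip_states_exact(self):
        pt = read_newick("((A:1,B:2):1,(C:0.5,D:1.5):2):0;")
        tips = {k: np.array([i * 1.0, -i * 2.0]) for i, k in enumerate("ABCD")}
        st = ancestral_states(pt, tips)
        for leaf in pt.tree.leaf_node_iter():
            assert np.array_equal(st[leaf], tips[leaf.taxon.label])

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(17)
        from morphomech import synthetic_data as S

        recs = [
            SpeciesRecord(f"sp{i}", "A" if i < 4 else "B", "other/unknown", "Jurassic", 100, 50, 25, 26, 50)
            for i in range(8)
        ]
        pt = read_newick(S.generate_tree(recs, seed=23))
        tips = {r.species_name: rng.normal(size=2) for r in recs}
        st = ancestral_states(pt, tips)
        obj = sq_change_objective(pt, st)
        internal = [n for n in pt.tree.preorder_node_iter() if not n.is_leaf()]
        brute = brute_force_states(pt, tips, [st[n] for n in internal])
        assert obj == pytest.approx(brute, abs=1e-6)
        assert obj <= brute + 1e-6

    def test_affine_equivariance(self):
        pt = read_newick("((A:1,B:2):1,(C:0.5,D:1.5):2):0;")
        rng = np.random.default_rng(2)
        tips = {k: rng.normal(size=2) for k in "ABCD"}
        M = np.array([[2.0, 0.5], [-1.0, 1.5]])
        c = np.array([3.0, -1.0])
        st = ancestral_states(pt, tips)
        st_t = ancestral_states(pt, {k: M @ v + c for k, v in tips.items()})
        for node in pt.tree.preorder_node_iter():
            assert np.allclose(st_t[node], M @ st[node] + c)

    def test_missing_tip_value_names_species(self):
        pt = read_newick("(A:1,B:1):0;")
        with pytest.raises(KeyError, match="B"):
            ancestral_states(pt, {"A": np.zeros(2)})


class TestOverlay:
    def _records(self, names):
        out = []
        for i, n in enumerate(names):
            out.append(
                SpeciesRecord(n, "Theropoda", "carnivore", "Jurassic", 105, 50 + i, 25, 26, 50)
            )
        return out

    def test_two_species_single_v_path(self):
        pt = read_newick("(A:1,B:1):0;")
        segments, tips, unconnected = phylo.phylomorphospace_overlay(pt, self._records(["A", "B"]))
        assert len(segments) == 2
        assert unconnected == []

    def test_pruning_preserves_path_lengths(self):
        pt = read_newick("((A:1,B:1):2,C:3):0;")
        pruned = pt.prune_to({"A", "C"})
        assert sorted(pruned.tip_labels()) == ["A", "C"]
        dists = pruned.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in pruned.tree.taxon_namespace if t.label in ("A", "C")}
        assert dists.distance(taxa["A"], taxa["C"]) == pytest.approx(6.0)

    def test_species_absent_from_tree_reported_unconnected(self):
        pt = read_newick("(A:1,B:1):0;")
        _, _, unconnected = phylo.phylomorphospace_overlay(pt, self._records(["A", "B", "Zeta"]))
        assert unconnected == ["Zeta"]

    def test_identical_tips_collapse_to_point(self):
        pt = read_newick("(A:1,B:1):0;")
        recs = [
            SpeciesRecord(n, "other", "other/unknown", "Jurassic", 105, 50, 25, 25, 50)
            for n in ("A", "B")
        ]
        segments, _, _ = phylo.phylomorphospace_overlay(pt, recs)
        for a, b in segments:
            assert np.allclose(a, b)

    def test_empty_intersection_rejected(self):
        pt = read_newick("(A:1,B:1):0;")
        with pytest.raises(ValueError):
            phylo.phylomorphospace_overlay(pt, self._records(["X", "Y"]))

    def test_plot_written(self, tmp_path):
        pt = read_newick("((A:1,B:1):1,C:2):0;")
        phylo.plot_phylomorphospace(pt, self._records(["A", "B", "C"]), tmp_path / "pms.png")
        assert (tmp_path / "pms.png").stat().st_size > 0
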