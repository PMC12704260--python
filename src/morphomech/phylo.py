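"""Phylogenies on the morphospace: Newick IO, ancestral states, overlays.

Internal-node positions are maximum-likelihood Brownian-motion estimates,
equivalent to weighted squared-change parsimony: they minimize the sum over
edges of (state change)^2 / branch length per coordinate.  The estimate is
computed exactly with the standard two-pass linear recursion (a post-order
pruning pass followed by a pre-order finalization pass); no optimizer is
involved.  Reconstruction operates on ternary-plot Cartesian coordinates,
so reconstructed ancestors are valid plot positions by convexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from morphomech.morphometrics import SpeciesRecord, proportions
from morphomech.morphospace import ternary_to_cartesian


@dataclass
class PhyloTree:
    """Rooted tree with unique tip labels and strictly positive branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(f"missing branch length above {edge.head_node}")
            if edge.length <= 0:
                raise ValueError(f"non-positive branch length {edge.length}")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def prune_to(self, keep: set[str]) -> "PhyloTree":
        """Prune to the given tips, merging branches through removed
        degree-2 nodes so path lengths are preserved."""
        present = set(self.tip_labels()) & set(keep)
        if not present:
            raise ValueError("no overlap between tree tips and requested species")
        tree = self.tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in present]
        tree.retain_taxa(taxa)
        return PhyloTree(tree)


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return PhyloTree(tree)


def write_newick(ptree: PhyloTree) -> str:
    """Serialize; round-trips topology, labels and branch lengths."""
    return ptree.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def ancestral_states(ptree: PhyloTree, tip_values: dict[str, np.ndarray]) -> dict:
    """ML Brownian-motion (= weighted squared-change parsimony) node states.

    ``tip_values`` maps species name to a coordinate vector; every tip must
    be present.  Returns a dict mapping dendropy node -> state vector; tip
    states equal the observed values exactly.
    """
    tree = ptree.tree
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in tip_values:
            raise KeyError(f"no tip value for species '{leaf.taxon.label}'")
    dim = len(np.atleast_1d(np.asarray(next(iter(tip_values.values()), None), float)))

    # post-order pruning pass: each node gets a conditional value x and an
    # effective variance v (its branch length plus the pooled child extra)
    x_down: dict = {}
    v_extra: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            x_down[node] = np.asarray(tip_values[node.taxon.label], float)
            v_extra[node] = 0.0
        else:
            ws, xs = [], []
            for ch in node.child_nodes():
                v = (ch.edge.length or 0.0) + v_extra[ch]
                ws.append(1.0 / v)
                xs.append(x_down[ch])
            ws = np.asarray(ws)
            x_down[node] = np.average(xs, axis=0, weights=ws)
            v_extra[node] = 1.0 / ws.sum()

    # pre-order finalization: combine the downpass estimate with the
    # parent's final state through the connecting branch
    states: dict = {}
    root = tree.seed_node
    states[root] = x_down[root]
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.is_leaf():
            states[node] = x_down[node]
            continue
        bl = node.edge.length
        w_down = 1.0 / v_extra[node] if v_extra[node] > 0 else None
        w_up = 1.0 / bl
        if w_down is None:
            states[node] = x_down[node]
        else:
            states[node] = (w_down * x_down[node] + w_up * states[node.parent_node]) / (
                w_down + w_up
            )
    if dim == 1:
        states = {k: np.atleast_1d(v) for k, v in states.items()}
    return states


def sq_change_objective(ptree: PhyloTree, states: dict) -> float:
    """Sum over edges of |state change|^2 / branch length."""
    total = 0.0
    for node in ptree.tree.preorder_node_iter():
        if node is ptree.tree.seed_node:
            continue
        d = np.asarray(states[node], float) - np.asarray(states[node.parent_node], float)
        total += float(np.dot(d, d)) / node.edge.length
    return total


def phylomorphospace_overlay(
    ptree: PhyloTree, records: list[SpeciesRecord]
) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict[str, np.ndarray], list[str]]:
    """Drawing primitives for a phylomorphospace plot in ternary coordinates.

    Returns (edge segments, tip label -> xy, unconnected species names).
    The tree is pruned to the species present in both inputs; species
    absent from the tree are returned as unconnected points.
    """
    by_name = {r.species_name: r for r in records}
    tips = set(ptree.tip_labels())
    shared = tips & set(by_name)
    if not shared:
        raise ValueError("no overlap between tree tips and species records")
    pruned = ptree.prune_to(shared)
    tip_xy = {
        name: ternary_to_cartesian(proportions(by_name[name])) for name in shared
    }
    states = ancestral_states(pruned, tip_xy)
    segments = []
    for node in pruned.tree.preorder_node_iter():
        if node is pruned.tree.seed_node:
            continue
        segments.append((np.asarray(states[node.parent_node]), np.asarray(states[node])))
    unconnected = sorted(set(by_name) - tips)
    return segments, tip_xy, unconnected


def plot_phylomorphospace(ptree: PhyloTree, records: list[SpeciesRecord], path) -> None:
    """Render the overlay (simplex frame, branches, clade-colored tips)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    segments, tip_xy, _ = phylomorphospace_overlay(ptree, records)
    fig, ax = plt.subplots(figsize=(7, 6.5))
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
    for a, b in segments:
        ax.plot([a[0], b[0]], [a[1], b[1]], "-", color="0.6", lw=0.7, zorder=1)
    clades = {r.species_name: r.clade for r in records}
    palette = {}
    cmap = plt.get_cmap("tab10")
    for name, xy in tip_xy.items():
        cl = clades[name]
        if cl not in palette:
            palette[cl] = cmap(len(palette) % 10)
        ax.scatter(*xy, s=14, color=palette[cl], zorder=2)
    for cl, color in palette.items():
        ax.scatter([], [], color=color, label=cl)
    ax.legend(fontsize=7, loc="upper right")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
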