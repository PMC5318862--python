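"""Edge-incidence arrays for fast branch-length algebra on rooted trees.

Every non-root node owns the edge to its parent.  A tree with ``n`` tips and
``m`` edges is summarised by a boolean ``(n, m)`` path matrix (which edges lie
on the root-to-tip path of each tip) plus an ``(m,)`` vector of edge lengths.
Patristic distances, rooted phylogenetic diversity and shared-branch sums then
reduce to boolean masking and dot products, which keeps permutation null
models cheap.
"""

from __future__ import annotations

import numpy as np

from .exceptions import NewickError

__all__ = ["TreeIndex"]


class TreeIndex:
    """Immutable numeric view of a rooted, branch-length-bearing dendropy tree.

    Tip order is lexicographic by label, so matrices built from the same tip
    set are directly comparable regardless of tree node order.
    """

    def __init__(self, tree):
        leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
        self.labels: tuple[str, ...] = tuple(lv.taxon.label for lv in leaves)
        self.index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.index) != len(self.labels):
            raise NewickError("duplicate tip labels in tree")

        edge_nodes = []
        edge_id = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                edge_id[id(nd)] = len(edge_nodes)
                edge_nodes.append(nd)
        lengths = np.empty(len(edge_nodes), dtype=float)
        for k, nd in enumerate(edge_nodes):
            if nd.edge.length is None:
                raise NewickError(
                    "tree has edges without branch lengths; lengths are required"
                )
            lengths[k] = float(nd.edge.length)

        paths = np.zeros((len(leaves), len(edge_nodes)), dtype=bool)
        for i, lv in enumerate(leaves):
            nd = lv
            while nd.parent_node is not None:
                paths[i, edge_id[id(nd)]] = True
                nd = nd.parent_node
        self.edge_lengths = lengths
        self.paths = paths
        self.depths = paths @ lengths

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def indices_of(self, labels) -> np.ndarray:
        """Map an iterable of tip labels to row indices (sorted, validated)."""
        try:
            idx = sorted(self.index[lab] for lab in labels)
        except KeyError as exc:
            raise KeyError(f"taxon {exc.args[0]!r} is not a tip of the tree") from None
        return np.asarray(idx, dtype=np.intp)

    def patristic(self) -> np.ndarray:
        """Full tip-by-tip patristic distance matrix (tip order = ``labels``)."""
        weighted = self.paths * self.edge_lengths
        shared = weighted @ self.paths.T
        d = self.depths[:, None] + self.depths[None, :] - 2.0 * shared
        np.fill_diagonal(d, 0.0)
        # clip tiny negative round-off
        np.clip(d, 0.0, None, out=d)
        return d

    def pd_rooted(self, idx: np.ndarray) -> float:
        """Root-inclusive phylogenetic diversity of the tip set ``idx``.

        Sum of edge lengths of the subtree spanning the tips and the root.
        """
        if len(idx) == 0:
            raise ValueError("rooted PD of an empty tip set is undefined")
        mask = self.paths[idx].any(axis=0)
        return float(self.edge_lengths[mask].sum())

    def shared_length(self, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        """Total length of edges lying in both root-inclusive spanning subtrees."""
        mask = self.paths[idx_a].any(axis=0) & self.paths[idx_b].any(axis=0)
        return float(self.edge_lengths[mask].sum())
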