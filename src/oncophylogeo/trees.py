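"""Rooted, dated genealogies stored as flat arrays.

A :class:`Tree` holds a binary rooted topology over ``n`` contemporaneous
tips (clones) with node heights measured backwards from the sampling time
(tips at height 0, in generations unless stated otherwise).  Nodes are
indexed ``0..n-1`` for tips and ``n..2n-2`` for internal nodes; the root is
whichever node has parent ``-1``.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = ["Tree", "mcc_tree"]


class Tree:
    """Binary rooted tree with node heights.

    Parameters
    ----------
    parent : array of int
        Parent index per node, ``-1`` for the root.
    heights : array of float
        Height (time before present) per node.
    tip_labels : sequence of str
        Labels for nodes ``0..n_tips-1``.
    """

    def __init__(self, parent, heights, tip_labels, validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.heights = np.asarray(heights, dtype=float).copy()
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if validate:
            self._validate()

    def _validate(self):
        if self.n_nodes != 2 * self.n_tips - 1:
            raise ValueError("binary tree requires 2*n_tips-1 nodes")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.heights < -1e-12):
            raise ValueError("negative node height")
        bl = self.branch_lengths
        if np.any(bl < -1e-9):
            raise ValueError("parent height below child height")

    # ------------------------------------------------------------------
    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to its parent (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_par = self.parent >= 0
        bl[has_par] = self.heights[self.parent[has_par]] - self.heights[has_par]
        return bl

    def children(self):
        ch = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        ch = self.children()
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(ch[node])
        return np.array(order[::-1], dtype=np.int64)

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1].copy()

    def copy(self) -> "Tree":
        return Tree(self.parent, self.heights, self.tip_labels, validate=False)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        return bool(np.all(np.abs(self.heights[: self.n_tips]) < tol))

    # ------------------------------------------------------------------
    def clade_masks(self) -> np.ndarray:
        """Bitmask of descendant tips per node (tip i contributes bit i)."""
        masks = np.zeros(self.n_nodes, dtype=object)
        for node in self.postorder():
            if node < self.n_tips:
                masks[node] = 1 << int(node)
            else:
                m = 0
                for c in np.flatnonzero(self.parent == node):
                    m |= masks[c]
                masks[node] = m
        return masks

    def mrca(self, tips) -> int:
        """Most recent common ancestor of a set of tip indices."""
        tips = list(tips)
        target = 0
        for t in tips:
            target |= 1 << int(t)
        masks = self.clade_masks()
        best, best_h = self.root, np.inf
        for node in range(self.n_nodes):
            if (masks[node] & target) == target and self.heights[node] < best_h:
                best, best_h = node, self.heights[node]
        return best

    def is_monophyletic(self, tips) -> bool:
        target = 0
        for t in tips:
            target |= 1 << int(t)
        return target in set(self.clade_masks()[self.n_tips:])

    def descendant_tips(self, node: int) -> list:
        mask = self.clade_masks()[node]
        return [i for i in range(self.n_tips) if mask >> i & 1]

    # ------------------------------------------------------------------
    def newick(self, include_labels: bool = True, digits: int = 10) -> str:
        ch = self.children()
        bl = self.branch_lengths

        def fmt(node):
            if node < self.n_tips:
                name = self.tip_labels[node] if include_labels else str(node)
            else:
                name = ""
            sub = ""
            if ch[node]:
                sub = "(" + ",".join(fmt(c) for c in ch[node]) + ")"
            if self.parent[node] >= 0:
                return f"{sub}{name}:{bl[node]:.{digits}g}"
            return f"{sub}{name}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a binary ultrametric-ish newick string.

        Uses dendropy for the heavy lifting, then converts edge lengths to
        heights (max root-to-tip distance minus root distance).
        """
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")
        dtree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = list(dtree.leaf_node_iter())
        n = len(leaves)
        tip_labels = [lf.taxon.label if lf.taxon else str(i) for i, lf in enumerate(leaves)]
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        nxt = n
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                continue
            index[id(nd)] = nxt
            nxt += 1
        if nxt != 2 * n - 1:
            raise ValueError("tree is not strictly binary")
        maxdist = max(lf.root_distance for lf in leaves)
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        heights = np.zeros(2 * n - 1)
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            heights[i] = maxdist - nd.root_distance
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        heights[np.abs(heights) < 1e-10] = 0.0
        return cls(parent, heights, tip_labels)

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick(), schema="newick")

    def to_nexus(self, path) -> None:
        self.to_dendropy().write(path=str(path), schema="nexus")

    @classmethod
    def from_nexus(cls, path) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(path=str(path), schema="nexus")
        return cls.from_newick(dtree.as_string(schema="newick"))

    def __repr__(self):
        return f"<Tree n_tips={self.n_tips} root_height={self.heights[self.root]:.4g}>"


def mcc_tree(trees, heights: str = "median"):
    """Maximum clade credibility summary of a posterior tree sample.

    Picks the sampled tree whose product of clade posterior frequencies is
    maximal and replaces node heights with per-clade medians (or means)
    across all trees containing the clade.  Per-node support values are
    returned alongside.

    Returns
    -------
    (Tree, dict)
        Summary tree and ``{node: support}`` for its internal nodes.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree sample")
    from collections import defaultdict

    counts: dict = defaultdict(int)
    height_samples: dict = defaultdict(list)
    all_masks = []
    for t in trees:
        masks = t.clade_masks()
        all_masks.append(masks)
        for node in range(t.n_tips, t.n_nodes):
            counts[masks[node]] += 1
            height_samples[masks[node]].append(t.heights[node])
    n = len(trees)
    best_score, best_idx = -np.inf, 0
    for i, t in enumerate(trees):
        score = 0.0
        for node in range(t.n_tips, t.n_nodes):
            score += np.log(counts[all_masks[i][node]] / n)
        if score > best_score:
            best_score, best_idx = score, i
    summary = trees[best_idx].copy()
    masks = all_masks[best_idx]
    agg = np.median if heights == "median" else np.mean
    support = {}
    for node in range(summary.n_tips, summary.n_nodes):
        summary.heights[node] = agg(height_samples[masks[node]])
        support[node] = counts[masks[node]] / n
    # enforce parent >= child after median substitution
    for node in summary.postorder():
        p = summary.parent[node]
        if p >= 0 and summary.heights[p] < summary.heights[node]:
            summary.heights[p] = summary.heights[node]
    return summary, support
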