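"""Time-calibrated phylogeny container and traversal utilities.

All comparative machinery in this package (contrasts, phylogenetic
covariances, clade definitions) runs on :class:`TimeTree`, a flat
array-based representation of a rooted tree with branch lengths in
million years (Myr).  Nodes are integer-indexed with tips occupying
``0 .. n_tips-1``; dendropy is used only for Newick serialisation and
parsing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree"]


@dataclass
class TimeTree:
    """Rooted time tree stored as parent/edge-length arrays.

    Parameters
    ----------
    parent
        ``(n_nodes,)`` integer array; ``parent[i]`` is the parent node of
        node ``i`` and ``-1`` marks the root.  Tips are nodes
        ``0..n_tips-1``.
    edge_length
        ``(n_nodes,)`` branch length (Myr) of the edge above each node;
        the root entry is 0.
    tip_labels
        Species identifiers, one per tip, aligned with tip indices.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    tip_labels: list[str]
    _children: list[list[int]] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        if self.parent.shape != self.edge_length.shape:
            raise ValueError("parent and edge_length must have equal length")
        if len(self.tip_labels) < 2:
            raise ValueError("a TimeTree needs at least 2 tips")

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def postorder(self) -> list[int]:
        """Node indices, children always before their parent."""
        order: list[int] = []
        stack = [self.root]
        ch = self.children()
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(ch[node])
        order.reverse()
        return order

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        d = np.zeros(self.n_nodes)
        for node in reversed(self.postorder()):  # preorder
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.edge_length[node]
        return d

    @property
    def crown_age(self) -> float:
        """Depth of the tips below the root (max tip depth, Myr)."""
        return float(self.depths()[: self.n_tips].max())

    def node_ages(self) -> np.ndarray:
        """Age of every node measured back from the present (Myr)."""
        d = self.depths()
        return d[: self.n_tips].max() - d

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        td = self.depths()[: self.n_tips]
        return bool(np.all(np.abs(td - td.max()) <= rtol * max(td.max(), 1.0)))

    def branching_times(self) -> np.ndarray:
        """Ages of the internal nodes, sorted descending (root first)."""
        ages = self.node_ages()[self.n_tips :]
        return np.sort(ages)[::-1]

    def tip_index(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"tip label {err} not in tree") from None

    # ------------------------------------------------------------------
    # comparative primitives
    # ------------------------------------------------------------------
    def tips_below(self) -> list[np.ndarray]:
        """For every node, the tip indices in its subtree."""
        sets: list[np.ndarray | None] = [None] * self.n_nodes
        ch = self.children()
        for node in self.postorder():
            if node < self.n_tips:
                sets[node] = np.array([node])
            else:
                sets[node] = np.concatenate([sets[c] for c in ch[node]])
        return sets  # type: ignore[return-value]

    def mrca(self, tips: np.ndarray) -> int:
        """Most recent common ancestor of a set of tip indices."""
        tips = np.asarray(tips, dtype=int)
        if tips.size == 0:
            raise ValueError("empty tip set has no MRCA")
        if tips.size == 1:
            return int(tips[0])
        anc = set()
        node = int(tips[0])
        while node != -1:
            anc.add(node)
            node = int(self.parent[node])
        depths = self.depths()
        best, best_depth = self.root, -1.0
        for t in tips[1:]:
            node = int(t)
            while node not in anc:
                node = int(self.parent[node])
            # restrict the ancestor set to this path and above
            path = set()
            m = node
            while m != -1:
                path.add(m)
                m = int(self.parent[m])
            anc &= path
        for node in anc:
            if depths[node] > best_depth:
                best, best_depth = node, depths[node]
        return int(best)

    def is_monophyletic(self, tips: np.ndarray) -> bool:
        tips = np.asarray(tips, dtype=int)
        below = self.tips_below()[self.mrca(tips)]
        return set(below.tolist()) == set(tips.tolist())

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths.

        ``V[i, j]`` is the depth (from the root) of the MRCA of tips i, j;
        the diagonal holds root-to-tip depths.
        """
        n = self.n_tips
        V = np.zeros((n, n))
        depths = self.depths()
        ch = self.children()
        sets: list[np.ndarray | None] = [None] * self.n_nodes
        for node in self.postorder():
            if node < n:
                sets[node] = np.array([node])
                V[node, node] = depths[node]
                continue
            groups = [sets[c] for c in ch[node]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    V[np.ix_(groups[a], groups[b])] = depths[node]
                    V[np.ix_(groups[b], groups[a])] = depths[node]
            sets[node] = np.concatenate(groups)
        return V

    # ------------------------------------------------------------------
    # pruning / collapsing
    # ------------------------------------------------------------------
    def extract_subtree(self, tip_labels) -> "TimeTree":
        """Subtree induced by a subset of tips, rooted at their MRCA.

        Unifurcations are suppressed and their branch lengths summed.
        """
        keep = self.tip_index(tip_labels)
        if keep.size < 2:
            raise ValueError("subtree needs at least 2 tips")
        keep_set = set(keep.tolist())
        ch = self.children()
        # number of kept tips below each node
        n_below = np.zeros(self.n_nodes, dtype=int)
        for node in self.postorder():
            if node < self.n_tips:
                n_below[node] = 1 if node in keep_set else 0
            else:
                n_below[node] = sum(n_below[c] for c in ch[node])

        root = self.mrca(keep)
        # kept tips are laid out at the front of the new index space
        kept_tips = [t for t in range(self.n_tips) if t in keep_set]
        n_new_tips = len(kept_tips)
        new_labels = [self.tip_labels[t] for t in kept_tips]
        tip_new_index = {t: i for i, t in enumerate(kept_tips)}
        out_parent = [-1] * n_new_tips
        out_len = [0.0] * n_new_tips
        next_internal = n_new_tips

        def descend(old_node: int, new_parent_idx: int, carried: float) -> None:
            nonlocal next_internal
            length = carried + (self.edge_length[old_node] if old_node != root else 0.0)
            if old_node < self.n_tips:
                ni = tip_new_index[old_node]
                out_parent[ni] = new_parent_idx
                out_len[ni] = length
                return
            kids = [c for c in ch[old_node] if n_below[c] > 0]
            if len(kids) == 1 and old_node != root:
                descend(kids[0], new_parent_idx, length)
                return
            ni = next_internal
            next_internal += 1
            out_parent.append(new_parent_idx)
            out_len.append(length if old_node != root else 0.0)
            for c in kids:
                descend(c, ni, 0.0)

        # root may itself be a tip only when keep.size == 1 (excluded above)
        import sys

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10 * self.n_nodes + 100))
        try:
            descend(root, -1, 0.0)
        finally:
            sys.setrecursionlimit(old_limit)
        return TimeTree(np.array(out_parent), np.array(out_len), new_labels)

    def collapse_to_clades(self, clades: dict[str, list[str]]) -> "TimeTree":
        """Collapse the tree to one tip per clade (tip = clade MRCA).

        Each clade's subtree is replaced by a single pendant edge ending at
        the clade's crown node, so the resulting tree is generally not
        ultrametric (clade crown ages differ).
        """
        if len(clades) < 2:
            raise ValueError("need at least 2 clades to collapse")
        mrcas = {cid: self.mrca(self.tip_index(tips)) for cid, tips in clades.items()}
        rep_tip = {cid: self.tip_index(tips)[0] for cid, tips in clades.items()}
        # build pruned tree on representative tips, then shorten each pendant
        # edge so the clade tip sits at the clade's crown age
        rep_labels = [self.tip_labels[rep_tip[cid]] for cid in clades]
        pruned = self.extract_subtree(rep_labels)
        ages = self.node_ages()
        out = TimeTree(
            pruned.parent.copy(), pruned.edge_length.copy(), list(clades.keys())
        )
        for i, cid in enumerate(clades):
            out.edge_length[i] = max(out.edge_length[i] - ages[mrcas[cid]], 0.0)
        out._children = None
        return out

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        ch = self.children()
        parts: list[str] = [""] * self.n_nodes

        for node in self.postorder():
            if node < self.n_tips:
                parts[node] = f"{self.tip_labels[node]}:{self.edge_length[node]:.10g}"
            else:
                inner = ",".join(parts[c] for c in ch[node])
                if self.parent[node] == -1:
                    parts[node] = f"({inner});"
                else:
                    parts[node] = f"({inner}):{self.edge_length[node]:.10g}"
        return parts[self.root]

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "TimeTree":
        leaves = [nd for nd in dtree.leaf_node_iter()]
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(leaves):
            index[nd] = i
        for j, nd in enumerate(internals):
            index[nd] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        elen = np.zeros(n)
        labels = []
        for nd in leaves:
            labels.append(nd.taxon.label if nd.taxon else f"t{index[nd]}")
        for nd, i in index.items():
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
                elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(parent, elen, labels)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read_newick(cls, path) -> "TimeTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def rescaled(self, crown_age: float) -> "TimeTree":
        """Copy with branch lengths scaled to the requested crown age."""
        if crown_age <= 0:
            raise ValueError("crown_age must be positive")
        f = crown_age / self.crown_age
        return TimeTree(self.parent.copy(), self.edge_length * f, list(self.tip_labels))
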