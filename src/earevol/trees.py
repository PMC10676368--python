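"""Rooted time-calibrated trees as index arrays.

dendropy handles Newick I/O; this module flattens a tree into preorder
arrays so that covariance matrices and branch-length transforms become
plain numpy operations.  All evolutionary-model code works on
:class:`TreeArrays`; user-facing functions also accept a dendropy
``Tree`` or a Newick string and convert on the fly.
"""
from __future__ import annotations

import numpy as np
import dendropy

__all__ = ["TreeArrays", "as_tree_arrays"]


class TreeArrays:
    """Preorder-indexed view of a rooted tree with branch lengths.

    Node 0 is the root.  ``parent[i]`` is the preorder index of node
    ``i``'s parent (-1 for the root) and ``blen[i]`` the length of the
    branch subtending node ``i`` (0 for the root).  Tip order is the
    order in which tips appear in the traversal; ``tip_labels`` records
    their taxon names.
    """

    def __init__(self, parent, blen, tip_nodes, tip_labels):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.tip_nodes = np.asarray(tip_nodes, dtype=int)
        self.tip_labels = list(tip_labels)
        self.n_nodes = self.parent.size
        self.n_tips = self.tip_nodes.size
        self._validate()
        self._index()

    def _validate(self):
        if self.n_nodes < 2 or self.n_tips < 2:
            raise ValueError("tree must have at least two tips")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the single root (preorder)")
        if np.any(self.parent[1:] >= np.arange(1, self.n_nodes)):
            raise ValueError("parents must precede children (preorder)")
        if np.any(self.blen[1:] <= 0):
            raise ValueError("all non-root branch lengths must be positive")
        if len(set(self.tip_labels)) != self.n_tips:
            raise ValueError("tip labels must be unique")

    def _index(self):
        n = self.n_nodes
        # node depths (root-to-node path lengths)
        self.depth = self.path_depths(self.blen)
        # ancestor-or-self incidence matrix
        anc = np.zeros((n, n), dtype=bool)
        for v in range(n):
            u = v
            while u != -1:
                anc[u, v] = True
                u = self.parent[u]
        self.anc = anc
        self.is_tip = np.zeros(n, dtype=bool)
        self.is_tip[self.tip_nodes] = True
        # MRCA node index for every node pair: the deepest common ancestor
        common = anc[:, :, None] & anc[:, None, :]          # (a, i, j)
        d = np.where(common, self.depth[:, None, None], -np.inf)
        self.mrca_nodes = np.argmax(d, axis=0)              # (n, n)
        self.mrca_tips = self.mrca_nodes[np.ix_(self.tip_nodes, self.tip_nodes)]
        self.tip_index = {lab: k for k, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------
    def path_depths(self, blen):
        """Root-to-node accumulated lengths for a branch-length vector."""
        blen = np.asarray(blen, dtype=float)
        depth = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            depth[v] = depth[self.parent[v]] + blen[v]
        return depth

    def vcv(self, blen=None):
        """Tip-tip covariance structure: shared root-to-MRCA path length.

        With the tree's own branch lengths this is the Brownian-motion
        design matrix C (diagonal = root-to-tip depth).
        """
        depth = self.depth if blen is None else self.path_depths(blen)
        return depth[self.mrca_tips].copy()

    def clade_tips(self, node):
        """Boolean mask over tips descending from (or equal to) ``node``."""
        return self.anc[node, self.tip_nodes]

    def branch_key(self, node):
        """Canonical identifier of the branch subtending ``node``."""
        return tuple(sorted(np.array(self.tip_labels)[self.clade_tips(node)]))

    def describe_branch(self, node):
        labs = sorted(np.array(self.tip_labels)[self.clade_tips(node)])
        if len(labs) == 1:
            return f"branch to {labs[0]}"
        return f"branch to clade of {len(labs)} tips ({labs[0]}..{labs[-1]})"

    def mrca_of_tips(self, labels):
        """Node index of the MRCA of the named tips."""
        ks = [self.tip_index[l] for l in labels]
        node = self.tip_nodes[ks[0]]
        for k in ks[1:]:
            node = self.mrca_nodes[node, self.tip_nodes[k]]
        return node

    def is_ultrametric(self, rel_tol=1e-6):
        d = self.depth[self.tip_nodes]
        return np.ptp(d) <= rel_tol * d.max()

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeArrays":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, blen, tip_nodes, tip_labels = [], [], [], []
        for i, nd in enumerate(nodes):
            if nd.parent_node is None:
                parent.append(-1)
                blen.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise ValueError("tree has branches without lengths")
                blen.append(float(nd.edge.length))
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else None
                if not lab:
                    raise ValueError("tip without a taxon label")
                tip_nodes.append(i)
                tip_labels.append(lab)
        return cls(parent, blen, tip_nodes, tip_labels)

    @classmethod
    def from_newick(cls, newick: str) -> "TreeArrays":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self, node_annotations=None) -> str:
        """Serialize back to Newick; ``node_annotations`` maps preorder
        node index to an internal-node label (e.g. an ancestral state)."""
        ann = node_annotations or {}
        children = [[] for _ in range(self.n_nodes)]
        for v in range(1, self.n_nodes):
            children[self.parent[v]].append(v)
        tip_lab = {int(n): lab for n, lab in zip(self.tip_nodes, self.tip_labels)}

        def render(v):
            if not children[v]:
                core = tip_lab[v].replace(" ", "_")
            else:
                core = "(" + ",".join(render(c) for c in children[v]) + ")"
                if v in ann:
                    core += str(ann[v])
            if v == 0:
                return core
            return f"{core}:{self.blen[v]:g}"

        return render(0) + ";"


def as_tree_arrays(tree) -> TreeArrays:
    """Coerce a TreeArrays, dendropy Tree, or Newick string/path."""
    if isinstance(tree, TreeArrays):
        return tree
    if isinstance(tree, dendropy.Tree):
        return TreeArrays.from_dendropy(tree)
    if isinstance(tree, str):
        s = tree.strip()
        if s.startswith("(") or s.endswith(";"):
            return TreeArrays.from_newick(s)
        with open(tree) as fh:
            return TreeArrays.from_newick(fh.read())
    raise TypeError(f"cannot interpret {type(tree)!r} as a tree")
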