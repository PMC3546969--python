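"""Unrooted phylogenetic trees with indexed branches.

Trees are stored with a reference traversal root (an arbitrary internal
node); because every substitution model used here is time-reversible, the
likelihood and all posterior quantities are invariant to where that root
is placed (pulley principle). A bifurcating Newick root is suppressed on
input and its two incident edges merged, so an unrooted binary tree with N
leaves exposes exactly 2N - 3 branches, indexed 0..N_b-1 in node order.

Newick reading/writing is delegated to dendropy.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np

DEFAULT_BRANCH_LENGTH = 0.1


class PhyloTree:
    """Tree with leaves 0..n_leaves-1 (labelled) and internal nodes after.

    Attributes
    ----------
    parent : ndarray of int
        Parent node of each node; -1 for the traversal root.
    length : ndarray of float
        Length of the edge to the parent (undefined for the root).
    labels : list of str
        Leaf labels, ``labels[i]`` for leaf node ``i``.
    """

    def __init__(self, parent: np.ndarray, length: np.ndarray, labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate leaf labels")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one traversal root")
        self.root = int(roots[0])
        self.n_nodes = len(self.parent)
        self.n_leaves = len(self.labels)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v != self.root:
                self.children[self.parent[v]].append(v)
        for v in range(self.n_leaves):
            if self.children[v] and v != self.root:
                raise ValueError("leaf nodes must not have children")
        if (self.length[np.arange(self.n_nodes) != self.root] < 0).any():
            raise ValueError("negative branch length")
        # branch b <-> non-root node branch_nodes[b]
        self.branch_nodes = np.array(
            [v for v in range(self.n_nodes) if v != self.root], dtype=int
        )
        self.leaf_index = {lab: i for i, lab in enumerate(self.labels)}

    # ------------------------------------------------------------------ basics

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def branches(self) -> list[tuple[int, int, float]]:
        """List of (parent, child, length), indexed by branch id."""
        return [
            (int(self.parent[v]), int(v), float(self.length[v]))
            for v in self.branch_nodes
        ]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.length.copy(), list(self.labels))

    def pendant_length(self, label: str) -> float:
        return float(self.length[self.leaf_index[label]])

    def leaf_path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        ia, ib = self.leaf_index[a], self.leaf_index[b]
        anc_a: dict[int, float] = {}
        v, d = ia, 0.0
        while v != -1:
            anc_a[v] = d
            d += self.length[v] if v != self.root else 0.0
            v = int(self.parent[v]) if v != self.root else -1
        v, d = ib, 0.0
        while True:
            if v in anc_a:
                return d + anc_a[v]
            d += self.length[v]
            v = int(self.parent[v])

    # ------------------------------------------------------------ dendropy I/O

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        # merge the two edges of a bifurcating root: the rooted position of
        # the tree carries no information under a reversible model
        dtree.suppress_unifurcations()
        seed = dtree.seed_node
        if len(seed.child_nodes()) == 2 and sum(1 for _ in dtree.leaf_node_iter()) == 2:
            # two-leaf tree: root at one leaf, a single connecting branch
            c1, c2 = seed.child_nodes()
            l1 = c1.edge.length if c1.edge.length is not None else 0.0
            l2 = c2.edge.length if c2.edge.length is not None else 0.0
            seed.remove_child(c1)
            seed.remove_child(c2)
            c1.add_child(c2)
            c2.edge.length = l1 + l2
            dtree.seed_node = c1
            c1.parent_node = None
        if len(seed.child_nodes()) == 2 and sum(1 for _ in dtree.leaf_node_iter()) > 2:
            c1, c2 = seed.child_nodes()
            keep, move = (c1, c2) if not c1.is_leaf() else (c2, c1)
            l1 = keep.edge.length if keep.edge.length is not None else 0.0
            l2 = move.edge.length if move.edge.length is not None else 0.0
            seed.remove_child(keep)
            seed.remove_child(move)
            keep.add_child(move)
            move.edge.length = l1 + l2
            dtree.seed_node = keep
            keep.parent_node = None

        dnodes = list(dtree.preorder_node_iter())
        leaves = [
            n for n in dnodes if not n.child_nodes() and n is not dtree.seed_node
        ]
        if dtree.seed_node.taxon is not None or (
            not dtree.seed_node.child_nodes()
        ):
            leaves.insert(0, dtree.seed_node)  # root placed at a leaf
        labels = []
        for n in leaves:
            lab = n.taxon.label if n.taxon is not None else n.label
            if lab is None:
                raise ValueError("unlabelled leaf in tree")
            labels.append(lab)
        index = {id(n): i for i, n in enumerate(leaves)}
        nxt = len(leaves)
        for n in dnodes:
            if id(n) not in index:
                index[id(n)] = nxt
                nxt += 1
        parent = np.full(nxt, -1, dtype=int)
        length = np.zeros(nxt)
        for n in dnodes:
            if n.parent_node is not None:
                parent[index[id(n)]] = index[id(n.parent_node)]
                el = n.edge.length
                if el is None:
                    warnings.warn(
                        "branch without length; defaulting to "
                        f"{DEFAULT_BRANCH_LENGTH}",
                        stacklevel=2,
                    )
                    el = DEFAULT_BRANCH_LENGTH
                length[index[id(n)]] = el
        return cls(parent, length, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.labels)
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.labels):
            dnodes[i].taxon = taxa.get_taxon(lab)
        for v in self.preorder():
            if v != self.root:
                dnodes[self.parent[v]].add_child(dnodes[v])
                dnodes[v].edge.length = float(self.length[v])
        dtree.seed_node = dnodes[self.root]
        return dtree

    def write_newick(self, path: str | Path | None = None) -> str:
        text = self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick file (or literal string ending in ';') into a tree.

    Branches without a stated length default to 0.1 with a warning.
    """
    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        try:
            exists = p.exists()
        except OSError:
            exists = False
        if exists:
            text = p.read_text()
        elif isinstance(source, str) and source.strip().endswith(";"):
            text = source
        else:
            raise FileNotFoundError(source)
    if not text or not text.strip():
        raise ValueError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    return tree.write_newick(path)


def prune_leaves(tree: PhyloTree, drop: list[str]) -> PhyloTree:
    """Remove the named leaves, suppressing resulting degree-2 nodes.

    Path lengths between all retained leaves are preserved (suppressed
    edges have their lengths summed).
    """
    drop_set = set(drop)
    missing = drop_set - set(tree.labels)
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    dtree = tree.to_dendropy()
    dtree.prune_taxa_with_labels(list(drop_set), suppress_unifurcations=True)
    return PhyloTree.from_dendropy(dtree)
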