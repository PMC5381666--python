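"""Indexed view of a rooted phylogeny.

Newick parsing, writing and tree simulation are delegated to dendropy;
this module flattens a rooted dendropy tree into integer-indexed parent /
branch-length arrays so that likelihood pruning, block identification and
path walks run on plain numpy without touching dendropy node objects in
inner loops.
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["IndexedTree", "read_newick", "write_newick"]


class IndexedTree:
    """A rooted tree with named nodes, indexed in preorder (root = 0).

    Attributes
    ----------
    parent : int array, parent index per node (-1 for the root)
    blen : float array, length of the branch above each node (0 for root)
    names : list of node names; internal nodes without a label get N<i>
    children : list of lists of child indices
    is_leaf : bool array
    """

    def __init__(self, parent: Sequence[int], blen: Sequence[float],
                 names: Sequence[str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.names = list(names)
        n = len(self.parent)
        if n == 0:
            raise ValueError("empty tree")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        self.n_nodes = n
        self.name_to_index = {nm: i for i, nm in enumerate(self.names)}
        if len(self.name_to_index) != n:
            raise ValueError("node names must be unique")
        # preorder guarantees parent[i] < i, so reversed order is a postorder
        self.postorder = np.arange(n - 1, -1, -1)
        self.depth = np.zeros(n, dtype=np.int64)      # edges from root
        self.dist_root = np.zeros(n)                  # branch-length distance
        for i in range(1, n):
            p = self.parent[i]
            self.depth[i] = self.depth[p] + 1
            self.dist_root[i] = self.dist_root[p] + self.blen[i]
        # plain-list mirrors: scalar indexing into numpy arrays dominates
        # the per-column-pair hot loops otherwise
        self._parent = self.parent.tolist()
        self._blen = self.blen.tolist()
        self._depth = self.depth.tolist()

    # -- basic queries ----------------------------------------------------
    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def lca(self, a: int, b: int) -> int:
        depth, parent = self._depth, self._parent
        while a != b:
            if depth[a] < depth[b]:
                b = parent[b]
            else:
                a = parent[a]
        return a

    def path(self, a: int, b: int) -> list[int]:
        """Node indices on the unique path a..b, inclusive, in order."""
        depth, parent = self._depth, self._parent
        up_a, up_b = [], []
        x, y = a, b
        while x != y:
            if depth[x] < depth[y]:
                up_b.append(y)
                y = parent[y]
            else:
                up_a.append(x)
                x = parent[x]
        return up_a + [x] + up_b[::-1]

    def path_distance(self, a: int, b: int) -> float:
        l = self.lca(a, b)
        return (self.dist_root[a] + self.dist_root[b]
                - 2.0 * self.dist_root[l])

    # -- conversion -------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "IndexedTree":
        parent, blen, names = [], [], []
        index = {}
        auto = 0
        seen = set()
        for nd in tree.preorder_node_iter():
            i = len(parent)
            index[nd] = i
            parent.append(index[nd.parent_node] if nd.parent_node else -1)
            blen.append(nd.edge.length if (nd.edge.length is not None
                                           and nd.parent_node) else 0.0)
            if nd.taxon is not None and nd.taxon.label:
                nm = nd.taxon.label
            elif nd.label:
                nm = nd.label
            else:
                nm = f"N{auto}"
                auto += 1
            while nm in seen:
                nm = f"N{auto}"
                auto += 1
            seen.add(nm)
            names.append(nm)
        return cls(parent, blen, names)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [None] * self.n_nodes
        for i in range(self.n_nodes):
            nd = tree.seed_node if i == 0 else dendropy.Node()
            if i > 0:
                nodes[self.parent[i]].add_child(nd)
                nd.edge.length = float(self.blen[i])
            if self.is_leaf[i]:
                nd.taxon = taxa.new_taxon(self.names[i])
            else:
                nd.label = self.names[i]
            nodes[i] = nd
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True).strip()


def read_newick(source: str) -> IndexedTree:
    """Read a rooted newick tree from a path or a newick string."""
    if source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    return IndexedTree.from_dendropy(tree)


def write_newick(tree: IndexedTree, path: str) -> None:
    with io.open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
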