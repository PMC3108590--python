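"""Leaf-labeled trees with polytomies: structure, I/O and generators.

The in-memory representation is a plain rooted node hierarchy
(:class:`TreeNode` / :class:`PhyloTree`); all comparison scores in
:mod:`lexitree.scores` interpret it as the corresponding unrooted tree, so
the placement of the root carries no information. Newick text is parsed
through dendropy and re-serialized directly.

Polytomies (internal nodes with more than two children) are first-class:
they encode the unresolved groupings of expert classifications such as the
Ethnologue catalogue, which lists languages by nested group membership
("classification paths") rather than as fully resolved binary trees.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Iterator, Sequence

import numpy as np

from .errors import LeafSetMismatchError, NewickParseError
from .matrix import DistanceMatrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "classification_to_tree",
    "read_classification_tsv",
    "prune_to_leaves",
    "prune_to_common_leaves",
    "random_binary_tree",
    "random_refinement",
    "resolution_fraction",
    "leaf_distance_matrix",
]


class TreeNode:
    """A node of a rooted tree; leaves carry labels, edges optional lengths."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<TreeNode {kind} {self.label!r}>"


class PhyloTree:
    """A rooted, leaf-labeled tree; internal nodes may have any degree.

    Leaf labels must be unique. Scores treat the tree as unrooted (a
    degree-2 root is transparent); the rooted form is kept because
    classification trees and simulation output are naturally rooted.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self.leaf_nodes()]
        if any(lbl is None or str(lbl).strip() == "" for lbl in labels):
            raise ValueError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dupes}")

    # -- traversal ------------------------------------------------------

    def nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal (iterative, so deep caterpillars are safe)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if not n.is_leaf]

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaf_nodes())

    def leaf_labels(self) -> list[str]:
        """Leaf labels in sorted order (the canonical ordering for matrices)."""
        return sorted(self.leaves)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def is_binary_rooted(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def clades(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` to the leaf set below that node (postorder)."""
        out: dict[int, frozenset[str]] = {}
        # children-first ordering without recursion
        order = list(self.nodes())
        for node in reversed(order):
            if node.is_leaf:
                out[id(node)] = frozenset([node.label])
            else:
                out[id(node)] = frozenset().union(
                    *(out[id(c)] for c in node.children)
                )
        return out

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def canonicalize(self) -> "PhyloTree":
        """Suppress unary nodes in place (summing branch lengths); return self."""
        while len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = None
        for node in list(self.nodes()):
            for child in list(node.children):
                while len(child.children) == 1:
                    grand = child.children[0]
                    if child.length is not None or grand.length is not None:
                        grand.length = (child.length or 0.0) + (grand.length or 0.0)
                    i = node.children.index(child)
                    node.children[i] = grand
                    grand.parent = node
                    child = grand
        return self

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves}>"


# -- Newick I/O ---------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick text (polytomies, branch lengths, quoted labels allowed)."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return PhyloTree(root).canonicalize()


_NEEDS_QUOTES = re.compile(r"[\s,():;\[\]']")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, path: str | None = None) -> str:
    """Serialize to Newick; branch lengths kept at full float precision."""

    def serialize(node: TreeNode) -> str:
        if node.is_leaf:
            out = _format_label(node.label)
        else:
            inner = ",".join(serialize(c) for c in node.children)
            out = f"({inner})"
            if node.label:
                out += _format_label(node.label)
        if node.length is not None and node.parent is not None:
            out += f":{float(node.length)!r}"
        return out

    text = serialize(tree.root) + ";"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


# -- classification paths ----------------------------------------------


def classification_to_tree(
    rows: Iterable[tuple[str, Sequence[str]]],
) -> PhyloTree:
    """Build a (generally multifurcating) tree from classification paths.

    Each row is ``(language_id, path)`` where *path* is the ordered sequence
    of nested group labels, e.g. ``("Austronesian", "Malayo-Polynesian",
    "Oceanic")``. Every distinct path prefix becomes one internal node; each
    language becomes a leaf under its full path. Polytomies arise wherever
    more than two languages or subgroups share a prefix.
    """
    root = TreeNode()
    index: dict[tuple[str, ...], TreeNode] = {(): root}
    seen: set[str] = set()
    for language_id, path in rows:
        if language_id in seen:
            raise ValueError(f"duplicate language id: {language_id!r}")
        seen.add(language_id)
        if not path:
            raise ValueError(f"empty classification path for {language_id!r}")
        prefix: tuple[str, ...] = ()
        for group in path:
            nxt = prefix + (str(group),)
            if nxt not in index:
                index[nxt] = index[prefix].add(TreeNode(label=str(group)))
            prefix = nxt
        index[prefix].add(TreeNode(label=language_id))
    if not seen:
        raise ValueError("no classification rows given")
    return PhyloTree(root).canonicalize()


def read_classification_tsv(path) -> PhyloTree:
    """Read a TSV with columns ``language`` and ``classification`` (``>``-separated)."""
    import pandas as pd

    from .errors import DataFormatError

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"language", "classification"}.issubset(df.columns):
        raise DataFormatError(
            "classification TSV needs columns 'language' and 'classification'"
        )
    rows = [
        (lang, tuple(part.strip() for part in cls.split(">")))
        for lang, cls in zip(df["language"], df["classification"])
    ]
    return classification_to_tree(rows)


# -- pruning ------------------------------------------------------------


def prune_to_leaves(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict *tree* to the leaves in *keep*, suppressing unary nodes."""
    keep = set(keep)

    def rebuild(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in keep:
                return TreeNode(node.label, node.length)
            return None
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        new = TreeNode(node.label, node.length)
        for k in kids:
            new.add(k)
        return new

    root = rebuild(tree.root)
    if root is None:
        raise LeafSetMismatchError("pruning removed every leaf")
    return PhyloTree(root).canonicalize()


def prune_to_common_leaves(
    t1: PhyloTree, t2: PhyloTree
) -> tuple[PhyloTree, PhyloTree]:
    """Restrict both trees to their shared leaf set."""
    common = t1.leaves & t2.leaves
    if len(common) < 2:
        raise LeafSetMismatchError(
            f"trees share only {len(common)} leaves; need at least 2"
        )
    return prune_to_leaves(t1, common), prune_to_leaves(t2, common)


# -- generators ---------------------------------------------------------


def random_binary_tree(leaves: Iterable[str], seed: int) -> PhyloTree:
    """A random fully resolved topology on the given leaf labels.

    Lineages are joined by uniform random sequential pair-joining
    (coalescent-style): at every step two of the surviving lineages are
    picked uniformly at random and merged. The draw is deterministic for a
    given seed. Branch lengths are left unset (topology-only null model).
    """
    labels = sorted(set(leaves))
    if len(labels) < 3:
        raise ValueError("random_binary_tree needs at least 3 leaves")
    rng = np.random.default_rng(seed)
    nodes: list[TreeNode] = [TreeNode(lbl) for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return PhyloTree(nodes[0])


def random_refinement(tree: PhyloTree, seed: int) -> PhyloTree:
    """Resolve every polytomy of *tree* into a random binary subtree.

    The output is binary and its bipartition set contains every bipartition
    of the input, i.e. it is a refinement in the strict sense: comparing a
    classification with one of its refinements must yield null generalized
    scores.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.nodes()):
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            joint = TreeNode()
            joint.add(a)
            joint.add(b)
            node.children = [
                c for k, c in enumerate(node.children) if k not in (i, j)
            ]
            joint.parent = node
            node.children.append(joint)
    return out


def resolution_fraction(tree: PhyloTree) -> float:
    """Fraction of internal nodes with exactly two children.

    1 for a fully binary rooted tree, 0 for a pure star: a summary of how
    much of a classification's structure is actually resolved.
    """
    internal = tree.internal_nodes()
    if not internal:
        raise ValueError("tree has no internal node")
    binary = sum(1 for n in internal if len(n.children) == 2)
    return binary / len(internal)


# -- path lengths -------------------------------------------------------


def leaf_distance_matrix(
    tree: PhyloTree, use_lengths: bool = True
) -> DistanceMatrix:
    """All pairwise leaf-to-leaf path lengths as a :class:`DistanceMatrix`.

    With ``use_lengths=False`` (or whenever an edge has no length) each edge
    counts 1. A tree with positive lengths yields an additive matrix, the
    regime in which distance-based reconstruction is exact.
    """
    labels = tree.leaf_labels()
    pos = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    # postorder accumulation of leaf->node distances
    below: dict[int, list[tuple[int, float]]] = {}
    order = list(tree.nodes())
    for node in reversed(order):
        if node.is_leaf:
            below[id(node)] = [(pos[node.label], 0.0)]
            continue
        child_maps = []
        for child in node.children:
            edge = child.length if (use_lengths and child.length is not None) else 1.0
            child_maps.append([(i, d + edge) for i, d in below.pop(id(child))])
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for i, di in child_maps[a]:
                    for j, dj in child_maps[b]:
                        values[i, j] = values[j, i] = di + dj
        below[id(node)] = [pair for cm in child_maps for pair in cm]
    return DistanceMatrix(tuple(labels), values)
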