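"""Distance-based tree inference.

Classic neighbor-joining (Saitou-Nei, with the Studier-Keppler Q-criterion)
plus a plug-in point for trees produced by external programs, so any
reconstruction algorithm can feed the scoring pipeline.

NJ is exact on additive matrices: if the input distances are realizable as
path lengths on a positively weighted binary tree, the algorithm returns
that tree, topology and branch lengths alike. Real lexical matrices are
never exactly additive, but this guarantee anchors the method and the
test-suite oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LeafSetMismatchError
from .matrix import DistanceMatrix
from .trees import PhyloTree, TreeNode, parse_newick, prune_to_leaves

__all__ = ["ReconstructionResult", "neighbor_joining", "load_external_tree"]


@dataclass(frozen=True)
class ReconstructionResult:
    """A reconstructed tree plus provenance.

    ``is_binary`` refers to the unrooted sense (every internal node of
    degree 3); externally loaded trees may be non-binary and are flagged.
    """

    tree: PhyloTree
    method_tag: str
    source_labels: tuple[str, ...]

    @property
    def is_binary(self) -> bool:
        root_deg = len(self.tree.root.children)
        others = [
            n for n in self.tree.internal_nodes() if n is not self.tree.root
        ]
        return root_deg in (2, 3) and all(len(n.children) == 2 for n in others)


def neighbor_joining(dm: DistanceMatrix) -> ReconstructionResult:
    """Classic NJ on a symmetric zero-diagonal matrix (n >= 3).

    At each step the pair (i, j) minimizing the Q-criterion
    ``(m - 2) d_ij - r_i - r_j`` is joined; ties are broken by the
    lexicographically smallest label pair (each cluster is keyed by the
    smallest leaf label it contains), so the output is deterministic across
    platforms. Negative branch lengths are clamped to zero with the length
    transferred to the sibling branch, preserving the pair's total length.
    The result is an unrooted binary tree, rooted for representation at the
    final three-way join.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(lbl) for lbl in dm.labels]
    keys = list(dm.labels)  # cluster sort keys: smallest contained leaf label

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, str, str] | None = None
        best_ij = (0, 1)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                ka, kb = sorted((keys[i], keys[j]))
                cand = (q, ka, kb)
                if best is None or cand < best:
                    best = cand
                    best_ij = (i, j)
        i, j = best_ij
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # reduced distances to the new cluster
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    root = TreeNode()
    if len(nodes) == 3:
        a, b, c = nodes
        la = max(0.0, (d[0, 1] + d[0, 2] - d[1, 2]) / 2)
        lb = max(0.0, (d[0, 1] + d[1, 2] - d[0, 2]) / 2)
        lc = max(0.0, (d[0, 2] + d[1, 2] - d[0, 1]) / 2)
        for node, length in ((a, la), (b, lb), (c, lc)):
            node.length = length
            root.add(node)
    return ReconstructionResult(
        tree=PhyloTree(root),
        method_tag="nj",
        source_labels=dm.labels,
    )


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    # at most one of the two can be negative (their sum is a distance >= 0)
    if vi < 0:
        return 0.0, vj + vi
    if vj < 0:
        return vi + vj, 0.0
    return vi, vj


def load_external_tree(
    path,
    labels: tuple[str, ...] | None = None,
    prune: bool = False,
    method_tag: str | None = None,
) -> ReconstructionResult:
    """Wrap a Newick tree produced by an external program for scoring.

    If *labels* is given the tree's leaves must match; extra leaves are
    removed when ``prune=True`` and are an error otherwise. Missing
    expected leaves are always an error. ``method_tag`` defaults to the
    file's stem.
    """
    import os

    with open(path, encoding="utf-8") as fh:
        tree = parse_newick(fh.read())
    if labels is not None:
        expected = set(labels)
        got = set(tree.leaves)
        missing = expected - got
        if missing:
            raise LeafSetMismatchError(
                f"external tree lacks expected leaves: {sorted(missing)}"
            )
        extra = got - expected
        if extra:
            if not prune:
                raise LeafSetMismatchError(
                    f"external tree has unexpected leaves {sorted(extra)}; "
                    "pass prune=True to drop them"
                )
            tree = prune_to_leaves(tree, expected)
    tag = method_tag or os.path.splitext(os.path.basename(str(path)))[0]
    return ReconstructionResult(
        tree=tree,
        method_tag=tag,
        source_labels=tuple(sorted(tree.leaves)),
    )
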