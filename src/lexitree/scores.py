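"""Tree-comparison scores: RF, QD and their generalizations GRF and GQD.

All scores are defined on the unrooted interpretation of the trees: the
elementary objects are the non-trivial bipartitions (splits) induced by
internal edges and the induced topologies of four-leaf subsets (quartets).

The standard scores are symmetric metrics:

* normalized Robinson-Foulds distance
  ``RF = (|E1| + |E2| - 2 * shared) / (|E1| + |E2|)`` over non-trivial
  bipartition sets E1, E2;
* normalized quartet distance ``QD = (B1 + B2 - 2s - d) / C(n, 4)`` where
  ``B1, B2`` count butterfly (resolved) quartets in each tree, ``s`` the
  quartets resolved identically in both, and ``d`` those resolved as
  conflicting butterflies.

Both penalize an inferred binary tree for *every* edge or quartet missing
from a partially resolved reference, even when the inferred tree merely
refines it. The generalized scores remove that bias and are deliberately
asymmetric in (reference, inferred):

* ``GRF(ref, inf) = 1 - compatible / |E(inf)|``: the fraction of the
  inferred tree's bipartitions that *contradict* the reference, where a
  bipartition B1|B2 is compatible with the reference iff for every
  reference split E1|E2 one of B1 <= E1, B1 <= E2, B2 <= E1, B2 <= E2 holds;
* ``GQD(ref, inf) = d / B(ref)``: conflicting butterflies normalized by the
  number of quartets the *reference* actually resolves, so the reference's
  star quartets are never counted as errors.

Both generalized scores are zero whenever the inferred tree is a refinement
of the reference.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable
from dataclasses import dataclass
from math import comb

import numpy as np

from .errors import LeafSetMismatchError, UndefinedScoreError
from .trees import PhyloTree

__all__ = [
    "Bipartition",
    "QuartetCensus",
    "internal_bipartitions",
    "is_compatible",
    "rf_distance",
    "quartet_topology",
    "quartet_census",
    "qd_distance",
    "grf_score",
    "gqd_score",
]


class Bipartition:
    """An unordered split of the full leaf set into two non-empty sides.

    Canonical form stores the side containing the lexicographically
    smallest label as ``side_a``, so equality and hashing are orientation
    free. A bipartition is *non-trivial* when both sides have at least two
    leaves (only those correspond to internal edges).
    """

    __slots__ = ("side_a", "side_b")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise ValueError("bipartition sides must be non-empty")
        if a & b:
            raise ValueError("bipartition sides must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        self.side_a = a
        self.side_b = b

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.side_a == other.side_a and self.side_b == other.side_b

    def __hash__(self) -> int:
        return hash((self.side_a, self.side_b))

    def __repr__(self) -> str:
        fmt = lambda side: ",".join(sorted(side))  # noqa: E731
        return f"{fmt(self.side_a)}|{fmt(self.side_b)}"


def internal_bipartitions(tree: PhyloTree) -> frozenset[Bipartition]:
    """Non-trivial bipartitions induced by internal edges of the unrooted tree.

    A degree-2 root contributes a single split (its two child edges are the
    same unrooted edge); a fully binary tree on n leaves yields exactly
    n - 3 bipartitions, a star none.
    """
    all_leaves = tree.leaves
    n = len(all_leaves)
    clades = tree.clades()
    out: set[Bipartition] = set()
    for node in tree.nodes():
        if node is tree.root:
            continue
        clade = clades[id(node)]
        if 2 <= len(clade) <= n - 2:
            out.add(Bipartition(clade, all_leaves - clade))
    return frozenset(out)


def is_compatible(split: Bipartition, tree: PhyloTree) -> bool:
    """Four-subset compatibility of a split with every split of *tree*.

    ``B1|B2`` is compatible with the tree iff for each tree split ``E1|E2``
    at least one of B1 <= E1, B1 <= E2, B2 <= E1, B2 <= E2 holds. A star
    tree (no internal edges) is vacuously compatible with anything.
    """
    if split.leaf_set != tree.leaves:
        raise LeafSetMismatchError("split is not over the tree's leaf set")
    b1, b2 = split.side_a, split.side_b
    for other in internal_bipartitions(tree):
        e1, e2 = other.side_a, other.side_b
        if not (b1 <= e1 or b1 <= e2 or b2 <= e1 or b2 <= e2):
            return False
    return True


def _check_same_leaves(t1: PhyloTree, t2: PhyloTree) -> frozenset[str]:
    if t1.leaves != t2.leaves:
        raise LeafSetMismatchError(
            "trees are over different leaf sets; prune to common leaves first"
        )
    return t1.leaves


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalized Robinson-Foulds distance (fraction of unshared splits).

    Two star trees have no splits to disagree on; that degenerate case is
    defined as distance 0.
    """
    _check_same_leaves(t1, t2)
    b1 = internal_bipartitions(t1)
    b2 = internal_bipartitions(t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return (denom - 2 * len(b1 & b2)) / denom


# -- quartets -----------------------------------------------------------

#: integer codes for induced quartet topologies over an index quadruple
#: (i, j, k, l): 0 = ij|kl, 1 = ik|jl, 2 = il|jk, 3 = star
_STAR = 3


def _topology_vector(tree: PhyloTree, order: list[str]) -> np.ndarray:
    """Induced topology code for every 4-subset of *order* (C(n,4) array).

    Any single split separating two of the four leaves from the other two
    fixes the quartet's butterfly topology, and all splits of one tree are
    pairwise compatible, so the first resolving split found is definitive.
    """
    n = len(order)
    quartets = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 4)),
        dtype=np.int64,
    ).reshape(-1, 4)
    topo = np.full(len(quartets), _STAR, dtype=np.int8)
    for split in internal_bipartitions(tree):
        memb = np.fromiter((lbl in split.side_a for lbl in order), bool, count=n)
        m = memb[quartets]
        todo = (topo == _STAR) & (m.sum(axis=1) == 2)
        if not todo.any():
            continue
        p01 = m[:, 0] == m[:, 1]
        p02 = m[:, 0] == m[:, 2]
        topo[todo & p01] = 0
        topo[todo & ~p01 & p02] = 1
        topo[todo & ~p01 & ~p02] = 2
    return topo


def quartet_topology(tree: PhyloTree, quartet: Iterable[str]) -> str:
    """Induced topology of one quartet: ``"AB|CD"``, ``"AC|BD"``, ``"AD|BC"``
    or ``"STAR"``, with A..D naming the four labels in the given order."""
    labels = list(quartet)
    if len(labels) != 4 or len(set(labels)) != 4:
        raise ValueError("quartet must be 4 distinct labels")
    missing = set(labels) - tree.leaves
    if missing:
        raise LeafSetMismatchError(f"labels not in tree: {sorted(missing)}")
    qset = set(labels)
    for split in internal_bipartitions(tree):
        inside = qset & split.side_a
        if len(inside) != 2:
            inside = qset & split.side_b
        if len(inside) != 2:
            continue
        a, b, c, d = labels
        if inside in ({a, b}, {c, d}):
            return "AB|CD"
        if inside in ({a, c}, {b, d}):
            return "AC|BD"
        return "AD|BC"
    return "STAR"


@dataclass(frozen=True)
class QuartetCensus:
    """Joint classification of all C(n,4) quartets of two trees.

    ``b1``/``b2``: butterflies in each tree; ``s``: quartets resolved
    identically in both; ``d``: resolved in both but conflicting;
    ``q``: total number of quartets.
    """

    b1: int
    b2: int
    s: int
    d: int
    q: int


def quartet_census(t1: PhyloTree, t2: PhyloTree) -> QuartetCensus:
    """Exhaustively classify every quartet of two trees on the same leaves."""
    leaves = _check_same_leaves(t1, t2)
    n = len(leaves)
    if n < 4:
        raise ValueError("quartet census needs at least 4 leaves")
    order = sorted(leaves)
    v1 = _topology_vector(t1, order)
    v2 = _topology_vector(t2, order)
    res1 = v1 != _STAR
    res2 = v2 != _STAR
    both = res1 & res2
    return QuartetCensus(
        b1=int(res1.sum()),
        b2=int(res2.sum()),
        s=int((both & (v1 == v2)).sum()),
        d=int((both & (v1 != v2)).sum()),
        q=comb(n, 4),
    )


def qd_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalized quartet distance: fraction of quartets whose induced
    topologies differ (butterfly vs conflicting butterfly, or butterfly vs
    star)."""
    c = quartet_census(t1, t2)
    return (c.b1 + c.b2 - 2 * c.s - c.d) / c.q


# -- generalized scores -------------------------------------------------


def grf_score(reference: PhyloTree, inferred: PhyloTree) -> float:
    """Generalized Robinson-Foulds score (asymmetric).

    Fraction of the inferred tree's bipartitions that are incompatible with
    the reference. Refinement edges are compatible by construction, so an
    inferred tree refining the reference scores 0; a star reference makes
    every inferred split vacuously compatible (score 0). A star *inferred*
    tree offers no bipartition to judge and is an error, not a perfect
    score.
    """
    _check_same_leaves(reference, inferred)
    splits = internal_bipartitions(inferred)
    if not splits:
        raise UndefinedScoreError(
            "GRF undefined: inferred tree has no internal edge"
        )
    compatible = sum(1 for s in splits if is_compatible(s, reference))
    return 1.0 - compatible / len(splits)


def gqd_score(reference: PhyloTree, inferred: PhyloTree) -> float:
    """Generalized quartet distance (asymmetric).

    Conflicting butterflies divided by the number of butterflies of the
    *reference*; quartets the reference leaves unresolved are never counted
    as errors. With a completely unresolved (star) reference there is
    nothing to contradict and the score is 0 by convention.
    """
    c = quartet_census(reference, inferred)
    if c.b1 == 0:
        return 0.0
    return c.d / c.b1
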