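"""Tree structure, Newick/classification I/O, splits, quartets and scores."""

import itertools

import dendropy
import networkx as nx
import numpy as np
import pytest

import lexitree as lt
from lexitree.errors import (
    LeafSetMismatchError,
    NewickParseError,
    UndefinedScoreError,
)


def quartet_oracle(tree, quartet):
    """Independent quartet topology via the four-point condition.

    Topological leaf-to-leaf distances are computed on a networkx graph
    built straight from the node hierarchy; the pairing with the strictly
    smallest distance sum is the butterfly, three equal sums mean a star.
    """
    g = nx.Graph()
    for node in tree.nodes():
        for child in node.children:
            g.add_edge(id(node), id(child))
    by_label = {n.label: id(n) for n in tree.leaf_nodes()}
    a, b, c, d = quartet
    dist = dict(nx.all_pairs_shortest_path_length(g))

    def dd(x, y):
        return dist[by_label[x]][by_label[y]]

    sums = [dd(a, b) + dd(c, d), dd(a, c) + dd(b, d), dd(a, d) + dd(b, c)]
    lo = min(sums)
    if sums.count(lo) > 1:
        return "STAR"
    return ["AB|CD", "AC|BD", "AD|BC"][sums.index(lo)]


def naive_qd(t1, t2):
    """Fraction of quartets with differing induced topologies, one by one."""
    leaves = sorted(t1.leaves)
    diffs = 0
    total = 0
    for q in itertools.combinations(leaves, 4):
        total += 1
        if quartet_oracle(t1, q) != quartet_oracle(t2, q):
            diffs += 1
    return diffs / total


class TestNewick:
    def test_parse_basic(self):
        t = lt.parse_newick("((a,b),(c,d));")
        assert t.leaves == {"a", "b", "c", "d"}
        assert len(lt.internal_bipartitions(t)) == 1

    def test_star_has_no_internal_bipartitions(self):
        assert lt.internal_bipartitions(lt.parse_newick("(a,b,c,d);")) == frozenset()

    @pytest.mark.parametrize("bad", ["((a,b", "((a,b),(a,c));", "(a,b))(;"])
    def test_parse_errors(self, bad):
        with pytest.raises(NewickParseError):
            lt.parse_newick(bad)

    def test_branch_lengths_and_quoted_labels(self):
        t = lt.parse_newick("(('my lang':0.5,b:1.25):0.1,c:2,d:3);")
        assert "my lang" in t.leaves
        lengths = {n.label: n.length for n in t.leaf_nodes()}
        assert lengths["b"] == pytest.approx(1.25)

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_preserves_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        t = lt.random_binary_tree([f"leaf{i}" for i in range(n)], seed)
        for node in t.nodes():
            if node is not t.root:
                node.length = float(rng.uniform(0.01, 5))
        back = lt.parse_newick(lt.write_newick(t))
        assert lt.internal_bipartitions(back) == lt.internal_bipartitions(t)
        d1 = lt.leaf_distance_matrix(t)
        d2 = lt.leaf_distance_matrix(back)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_single_leaf_and_star_round_trip(self):
        assert lt.parse_newick("a;").leaves == {"a"}
        star = lt.parse_newick("(a,b,c,d,e);")
        back = lt.parse_newick(lt.write_newick(star))
        assert lt.internal_bipartitions(back) == frozenset()
        assert back.leaves == star.leaves

    def test_unary_nodes_suppressed(self):
        t = lt.parse_newick("((((a,b))));")
        assert len(t.root.children) == 2


class TestClassificationPaths:
    def test_shared_prefixes_build_polytomies(self):
        t = lt.classification_to_tree([
            ("l1", ("X", "Y")),
            ("l2", ("X", "Y")),
            ("l3", ("X", "Z")),
        ])
        assert t.leaves == {"l1", "l2", "l3"}
        assert t.root.label == "X"
        kids = {tuple(sorted(c.label for c in n.children if c.is_leaf))
                for n in t.internal_nodes()}
        assert ("l1", "l2") in kids

    def test_single_shared_path_is_star(self):
        t = lt.classification_to_tree([
            (f"l{i}", ("Fam",)) for i in range(5)
        ])
        assert lt.resolution_fraction(t) == 0.0

    def test_distinct_paths_make_root_star(self):
        t = lt.classification_to_tree([
            ("l1", ("A",)), ("l2", ("B",)), ("l3", ("C",))
        ])
        assert lt.internal_bipartitions(t) == frozenset()

    def test_duplicate_language_raises(self):
        with pytest.raises(ValueError):
            lt.classification_to_tree([("l1", ("X",)), ("l1", ("Y",))])


class TestPruning:
    def test_identical_leaf_sets_unchanged(self):
        t1 = lt.parse_newick("((a,b),(c,d));")
        t2 = lt.parse_newick("((a,c),(b,d));")
        p1, p2 = lt.prune_to_common_leaves(t1, t2)
        assert lt.internal_bipartitions(p1) == lt.internal_bipartitions(t1)

    def test_extra_leaf_removed_and_node_suppressed(self):
        t1 = lt.parse_newick("(((a,x),b),(c,d));")
        t2 = lt.parse_newick("((a,b),(c,d));")
        p1, p2 = lt.prune_to_common_leaves(t1, t2)
        assert p1.leaves == {"a", "b", "c", "d"}
        assert lt.internal_bipartitions(p1) == lt.internal_bipartitions(t2)

    def test_disjoint_leaf_sets_raise(self):
        with pytest.raises(LeafSetMismatchError):
            lt.prune_to_common_leaves(
                lt.parse_newick("(a,b,c);"), lt.parse_newick("(x,y,z);")
            )


class TestBipartitionsAndCompatibility:
    def test_binary_tree_has_n_minus_3_bipartitions(self):
        t = lt.parse_newick("(((a,b),c),((d,e),f));")
        assert len(lt.internal_bipartitions(t)) == 3

    def test_five_leaf_bipartitions_by_hand(self):
        t = lt.parse_newick("((a,b),(c,d),e);")
        expected = {
            lt.Bipartition({"a", "b"}, {"c", "d", "e"}),
            lt.Bipartition({"c", "d"}, {"a", "b", "e"}),
        }
        assert lt.internal_bipartitions(t) == frozenset(expected)

    def test_compatibility_with_star_is_vacuous(self):
        star = lt.parse_newick("(a,b,c,d,e);")
        split = lt.Bipartition({"a", "b"}, {"c", "d", "e"})
        assert lt.is_compatible(split, star)

    def test_subset_rule_by_hand(self):
        t = lt.parse_newick("((a,b,c),(d,e));")  # only split abc|de
        assert lt.is_compatible(lt.Bipartition({"a", "b"}, {"c", "d", "e"}), t)
        t2 = lt.parse_newick("((a,b),(c,d,e));")  # only split ab|cde
        assert not lt.is_compatible(lt.Bipartition({"a", "c"}, {"b", "d", "e"}), t2)

    def test_leaf_set_mismatch(self):
        t = lt.parse_newick("((a,b),(c,d));")
        with pytest.raises(LeafSetMismatchError):
            lt.is_compatible(lt.Bipartition({"a", "b"}, {"c", "x"}), t)


class TestStandardDistances:
    def test_identical_trees(self):
        t = lt.parse_newick("((a,b),(c,d),(e,f));")
        assert lt.rf_distance(t, t) == 0.0
        assert lt.qd_distance(t, t) == 0.0

    def test_four_leaf_conflict(self):
        t1 = lt.parse_newick("((a,b),(c,d));")
        t2 = lt.parse_newick("((a,c),(b,d));")
        assert lt.rf_distance(t1, t2) == 1.0
        assert lt.qd_distance(t1, t2) == 1.0

    def test_five_leaf_worked_example(self):
        t1 = lt.parse_newick("((a,b),c,(d,e));")
        t2 = lt.parse_newick("((a,c),b,(d,e));")
        assert lt.rf_distance(t1, t2) == pytest.approx(0.5)
        c = lt.quartet_census(t1, t2)
        assert (c.b1, c.b2, c.s, c.d) == (5, 5, 3, 2)
        assert lt.qd_distance(t1, t2) == pytest.approx(0.4)

    def test_both_stars_at_distance_zero(self):
        s = lt.parse_newick("(a,b,c,d);")
        assert lt.rf_distance(s, s) == 0.0

    def test_star_vs_binary_census(self):
        star = lt.parse_newick("(a,b,c,d,e);")
        t = lt.parse_newick("((a,b),(c,d),e);")
        c = lt.quartet_census(star, t)
        assert c.b1 == 0 and c.s == 0 and c.d == 0

    def test_leaf_mismatch_raises(self):
        with pytest.raises(LeafSetMismatchError):
            lt.rf_distance(
                lt.parse_newick("((a,b),(c,d));"), lt.parse_newick("((a,b),(c,x));")
            )

    @pytest.mark.parametrize("seed", range(15))
    def test_rf_agrees_with_dendropy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        t1 = lt.random_binary_tree([f"l{i}" for i in range(n)], seed)
        t2 = lt.random_binary_tree([f"l{i}" for i in range(n)], seed + 100)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=lt.write_newick(t1), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=lt.write_newick(t2), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        raw = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert lt.rf_distance(t1, t2) == pytest.approx(raw / (2 * (n - 3)))


class TestQuartetTopology:
    def test_star_tree_all_star(self):
        star = lt.parse_newick("(a,b,c,d,e);")
        for q in itertools.combinations(sorted(star.leaves), 4):
            assert lt.quartet_topology(star, q) == "STAR"

    def test_by_construction(self):
        t = lt.parse_newick("((a,b),(c,d));")
        assert lt.quartet_topology(t, ("a", "b", "c", "d")) == "AB|CD"
        assert lt.quartet_topology(t, ("a", "c", "b", "d")) == "AC|BD"

    def test_caterpillar_restriction(self):
        t = lt.parse_newick("(a,(b,(c,(d,e))));")
        assert lt.quartet_topology(t, ("a", "b", "d", "e")) == "AB|CD"

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_four_point_oracle(self, seed):
        t = lt.random_binary_tree([f"l{i}" for i in range(8)], seed)
        t = lt.degrade_classification(t, 0.3, seed)  # add polytomies
        for q in itertools.combinations(sorted(t.leaves), 4):
            got = lt.quartet_topology(t, q)
            assert got == quartet_oracle(t, q)

    def test_unknown_label_raises(self):
        t = lt.parse_newick("((a,b),(c,d));")
        with pytest.raises(LeafSetMismatchError):
            lt.quartet_topology(t, ("a", "b", "c", "x"))


class TestGeneralizedScores:
    def test_grf_worked_example(self):
        reference = lt.parse_newick("((a,b),c,d,e);")
        inferred = lt.parse_newick("((a,c),b,(d,e));")
        assert lt.grf_score(reference, inferred) == pytest.approx(0.5)

    def test_gqd_worked_example(self):
        reference = lt.parse_newick("((a,b),(c,d));")
        inferred = lt.parse_newick("((a,c),(b,d));")
        assert lt.gqd_score(reference, inferred) == 1.0

    def test_star_reference_scores_zero(self):
        star = lt.parse_newick("(a,b,c,d,e);")
        binary = lt.parse_newick("((a,b),(c,d),e);")
        assert lt.grf_score(star, binary) == 0.0
        assert lt.gqd_score(star, binary) == 0.0

    def test_star_inferred_is_undefined_for_grf(self):
        star = lt.parse_newick("(a,b,c,d,e);")
        binary = lt.parse_newick("((a,b),(c,d),e);")
        with pytest.raises(UndefinedScoreError):
            lt.grf_score(binary, star)

    def test_asymmetry(self):
        reference = lt.parse_newick("((a,b),c,d,e);")
        inferred = lt.parse_newick("((a,c),b,(d,e));")
        assert lt.grf_score(reference, inferred) != lt.grf_score(inferred, reference)

    @pytest.mark.parametrize("seed", range(10))
    def test_refinement_scores_zero(self, seed):
        t = lt.random_binary_tree([f"l{i}" for i in range(12)], seed)
        collapsed = lt.degrade_classification(t, 0.5, seed)
        refined = lt.random_refinement(collapsed, seed + 1)
        assert lt.grf_score(collapsed, refined) == 0.0
        assert lt.gqd_score(collapsed, refined) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_gqd_monotone_under_reference_coarsening(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 14))
        ref = lt.random_binary_tree([f"l{i}" for i in range(n)], seed)
        inferred = lt.random_binary_tree([f"l{i}" for i in range(n)], seed + 50)
        score_full = lt.gqd_score(ref, inferred)
        for p in (0.3, 0.7, 1.0):
            coarser = lt.degrade_classification(ref, p, seed)
            # absolute conflict count can only shrink when splits vanish
            c_full = lt.quartet_census(ref, inferred)
            c_coarse = lt.quartet_census(coarser, inferred)
            assert c_coarse.d <= c_full.d
        assert 0.0 <= score_full <= 1.0


class TestRandomTrees:
    def test_bipartition_count_and_determinism(self):
        leaves = [f"l{i}" for i in range(10)]
        t = lt.random_binary_tree(leaves, 5)
        assert len(lt.internal_bipartitions(t)) == len(leaves) - 3
        t2 = lt.random_binary_tree(leaves, 5)
        assert lt.internal_bipartitions(t) == lt.internal_bipartitions(t2)
        t3 = lt.random_binary_tree(leaves, 6)
        assert lt.internal_bipartitions(t) != lt.internal_bipartitions(t3)

    def test_uniform_law_on_four_taxa(self):
        counts = {"AB|CD": 0, "AC|BD": 0, "AD|BC": 0}
        for seed in range(10_000):
            t = lt.random_binary_tree(["a", "b", "c", "d"], seed)
            counts[lt.quartet_topology(t, ("a", "b", "c", "d"))] += 1
        for topo, c in counts.items():
            assert c / 10_000 == pytest.approx(1 / 3, abs=0.02), topo

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            lt.random_binary_tree(["a", "b"], 0)

    def test_refinement_of_binary_is_identical(self):
        t = lt.random_binary_tree([f"l{i}" for i in range(8)], 3)
        r = lt.random_refinement(t, 9)
        assert lt.internal_bipartitions(r) == lt.internal_bipartitions(t)

    def test_refinement_of_star_is_binary(self):
        star = lt.parse_newick("(a,b,c,d,e,f);")
        r = lt.random_refinement(star, 4)
        assert len(lt.internal_bipartitions(r)) == 6 - 3
        assert lt.grf_score(star, r) == 0.0


class TestResolutionFraction:
    def test_extremes(self):
        assert lt.resolution_fraction(lt.parse_newick("((a,b),(c,d));")) == 1.0
        assert lt.resolution_fraction(lt.parse_newick("(a,b,c,d,e);")) == 0.0

    def test_mixed_by_hand(self):
        t = lt.parse_newick("((a,b),(c,d,e));")
        assert lt.resolution_fraction(t) == pytest.approx(2 / 3)
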