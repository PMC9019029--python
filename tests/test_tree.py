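"""Tree inference, rooting, quartet distance, Newick I/O."""

import itertools

import dendropy
import numpy as np
import pytest

from betapipe.distance import DistanceMatrix
from betapipe.tree import (
    SearchConfig,
    fit_branch_lengths,
    fitch_margoliash,
    is_monophyletic,
    neighbor_joining,
    parse_newick,
    quartet_distance,
    read_newick,
    root_with_outgroup,
    sibling_fraction,
    tree_to_newick,
    write_newick,
)


def random_binary_tree(n: int, seed: int, bl=(0.5, 2.0)) -> dendropy.Tree:
    """Random unrooted binary tree by sequential joins (test generator)."""
    rng = np.random.default_rng(seed)
    items = [f"t{i}:{rng.uniform(*bl):.6f}" for i in range(n)]
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        a, b = items[i], items[j]
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(f"({a},{b}):{rng.uniform(*bl):.6f}")
    nwk = "(" + ",".join(items) + ");"
    t = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    t.is_rooted = False
    return t


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return DistanceMatrix(labels, vals)


def quartet_topology_oracle(tree: dendropy.Tree, quartet) -> frozenset:
    """Independent quartet extraction via bipartitions (not path lengths)."""
    t = tree.clone(depth=1)
    t.deroot()
    quartet = set(quartet)
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()} & quartet
        if len(below) == 2:
            return frozenset([frozenset(below), frozenset(quartet - below)])
    return frozenset()  # unresolved (cannot happen for binary trees)


def brute_quartet_distance(t1, t2) -> int:
    labels = sorted({lf.taxon.label for lf in t1.leaf_node_iter()})
    count = 0
    for q in itertools.combinations(labels, 4):
        if quartet_topology_oracle(t1, q) != quartet_topology_oracle(t2, q):
            count += 1
    return count


HAND_MATRIX = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array(
        [
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ]
    ),
)
HAND_TREE = parse_newick("((A:1,B:2):1,(C:3,D:4));")


class TestFitchMargoliash:
    def test_recovers_hand_built_additive_matrix(self):
        t = fitch_margoliash(HAND_MATRIX, SearchConfig(jumbles=3, seed=0))
        assert quartet_distance(t, HAND_TREE) == 0
        # branch lengths reproduce the generating tree: path lengths match
        fitted = tree_distance_matrix(t).reorder(HAND_MATRIX.labels)
        assert np.allclose(fitted.values, HAND_MATRIX.values, atol=1e-9)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        t = fitch_margoliash(dm, SearchConfig(jumbles=1, seed=0))
        fitted = tree_distance_matrix(t).reorder(dm.labels)
        # a=(ab+ac-bc)/2=0.1, b=0.2, c=0.4 -> additive, exact fit
        assert np.allclose(fitted.values, dm.values, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        truth = random_binary_tree(n, seed=seed + 100)
        dm = tree_distance_matrix(truth)
        fm = fitch_margoliash(dm, SearchConfig(jumbles=5, seed=seed))
        nj = neighbor_joining(dm)
        assert quartet_distance(fm, truth) == 0
        assert quartet_distance(nj, truth) == 0

    def test_final_sse_not_worse_than_nj_topology(self):
        rng = np.random.default_rng(42)
        for rep in range(5):
            n = 9
            truth = random_binary_tree(n, seed=rep)
            dm = tree_distance_matrix(truth)
            noise = rng.normal(0, 0.05, (n, n))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            noisy = DistanceMatrix(dm.labels, np.abs(dm.values + noise))
            fm = fitch_margoliash(noisy, SearchConfig(jumbles=3, seed=rep))
            _, sse_fm = fit_branch_lengths(noisy, fm)
            _, sse_nj = fit_branch_lengths(noisy, neighbor_joining(noisy))
            assert sse_fm <= sse_nj + 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        n = 8
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals[iu] = rng.uniform(0.01, 0.05, iu[0].size)
        vals += vals.T
        dm = DistanceMatrix([f"t{i}" for i in range(n)], vals)
        a = tree_to_newick(fitch_margoliash(dm, SearchConfig(jumbles=3, seed=5)))
        b = tree_to_newick(fitch_margoliash(dm, SearchConfig(jumbles=3, seed=5)))
        assert a == b

    def test_rejects_tiny_matrices(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            fitch_margoliash(dm)


class TestRooting:
    def test_single_outgroup_roots_on_pendant_edge(self):
        t = parse_newick("((a:1,b:1):1,(c:1,og:4):1);")
        rooted = root_with_outgroup(t, ["og"])
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [{lf.taxon.label for lf in c.leaf_iter()} for c in children]
        assert {"og"} in sides

    def test_sibling_outgroups_root_on_stem(self):
        t = parse_newick("(((a:1,b:1):1,c:1):1,(og1:1,og2:1):2);")
        rooted = root_with_outgroup(t, ["og1", "og2"])
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert {"og1", "og2"} in sides

    def test_non_monophyletic_outgroup_rejected(self):
        t = parse_newick("((og1:1,a:1):1,(og2:1,b:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(t, ["og1", "og2"])


class TestMonophylyAndSiblings:
    TREE = parse_newick("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,og:5);")

    def test_full_ingroup_is_monophyletic(self):
        assert is_monophyletic(self.TREE, ["a1", "a2", "b1", "b2"], ["og"])

    def test_single_leaf_is_monophyletic(self):
        assert is_monophyletic(self.TREE, ["a1"], ["og"])

    def test_split_pair_is_not(self):
        assert not is_monophyletic(self.TREE, ["a1", "b1"], ["og"])

    def test_overlap_with_outgroup_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            is_monophyletic(self.TREE, ["a1", "og"], ["og"])

    def test_sibling_fraction_counts_cherries(self):
        t = parse_newick("((a:1,a2:1):1,(b:1,c:1):1);")
        assert sibling_fraction(t, [("a", "a2")]) == 1.0
        assert sibling_fraction(t, [("a", "b")]) == 0.0
        assert sibling_fraction(t, [("a", "a2"), ("b", "c"), ("a", "c")]) == pytest.approx(2 / 3)

    def test_missing_label_rejected(self):
        t = parse_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="absent"):
            sibling_fraction(t, [("a", "zzz")])


class TestQuartetDistance:
    def test_identical_trees(self):
        t = random_binary_tree(7, seed=0)
        assert quartet_distance(t, t) == 0

    def test_single_quartet_swap(self):
        t1 = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert quartet_distance(t1, t2) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bipartition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        t1 = random_binary_tree(n, seed=1000 + seed)
        t2 = random_binary_tree(n, seed=2000 + seed)
        assert quartet_distance(t1, t2) == brute_quartet_distance(t1, t2)

    def test_metric_axioms_on_random_triples(self):
        for seed in range(5):
            ts = [random_binary_tree(7, seed=3000 + 10 * seed + i) for i in range(3)]
            d01 = quartet_distance(ts[0], ts[1])
            d12 = quartet_distance(ts[1], ts[2])
            d02 = quartet_distance(ts[0], ts[2])
            assert d01 == quartet_distance(ts[1], ts[0])
            assert d02 <= d01 + d12
            assert quartet_distance(ts[0], ts[0]) == 0

    def test_leaf_set_mismatch_rejected(self):
        t1 = random_binary_tree(5, seed=1)
        t2 = random_binary_tree(6, seed=2)
        with pytest.raises(ValueError, match="leaf sets differ"):
            quartet_distance(t1, t2)


class TestNewickIO:
    def test_round_trip_simple(self, tmp_path):
        t = parse_newick("((A:1,B:2):1,C:3);")
        path = tmp_path / "t.nwk"
        write_newick(t, str(path))
        back = read_newick(str(path))
        assert quartet_distance(back, t) == 0
        pdm = tree_distance_matrix(back)
        assert pdm.get("A", "B") == pytest.approx(3.0)

    def test_label_with_space_is_quoted_and_recovered(self, tmp_path):
        t = parse_newick("(('PI 123456':1,B:2):1,C:3);")
        path = tmp_path / "q.nwk"
        write_newick(t, str(path))
        assert "'PI 123456'" in path.read_text()
        back = read_newick(str(path))
        labels = {lf.taxon.label for lf in back.leaf_node_iter()}
        assert "PI 123456" in labels

    def test_underscores_survive_round_trip(self, tmp_path):
        t = parse_newick("((acc_1_a:1,acc_1_b:1):1,other:2);")
        path = tmp_path / "u.nwk"
        write_newick(t, str(path))
        back = read_newick(str(path))
        labels = {lf.taxon.label for lf in back.leaf_node_iter()}
        assert "acc_1_a" in labels

    def test_malformed_string_rejected(self):
        with pytest.raises(ValueError, match="parse error"):
            parse_newick("((A:1,B:2):1,C:3;")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A:1,A:2):1,C:3);")
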