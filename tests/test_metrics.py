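"""Evaluation statistics: parsimony annotation, triplets, purity, distances,
bootstrap, NJ baseline."""

import itertools

import networkx as nx
import numpy as np
import pytest

from lintrace.core import MISSING, CharacterMatrix, LineageTree
from lintrace.greedy import build_greedy
from lintrace.metrics import (allelic_distance, annotate_ancestral_states,
                              binary_identity_dissimilarity,
                              bootstrap_characters, mean_majority_vote,
                              meta_purity, neighbor_joining, parsimony_score,
                              phylogenetic_distance, triplets_correct,
                              tree_diameter)


def _tree_from_edges(edges, root):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return LineageTree(g, root)


def _balanced_tree(leaves):
    """Caterpillar-free balanced binary tree over the given leaf names."""
    g = nx.DiGraph()
    nodes = list(leaves)
    counter = itertools.count()
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            parent = f"i{next(counter)}"
            g.add_edge(parent, nodes[i])
            g.add_edge(parent, nodes[i + 1])
            nxt.append(parent)
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return LineageTree(g, nodes[0])


class TestAnnotateAncestral:
    def test_single_shared_state_one_origin(self):
        tree = _balanced_tree(["a", "b", "c", "d"])
        m = CharacterMatrix([[5]] * 4, ["a", "b", "c", "d"])
        ann = annotate_ancestral_states(tree, m)
        assert parsimony_score(ann) == 1  # mutates once below the root

    def test_two_disjoint_clades_two_origins(self):
        tree = _balanced_tree(["a", "b", "c", "d"])
        m = CharacterMatrix([[7], [7], [0], [7]], ["a", "b", "c", "d"])
        # clade {a,b} carries 7; c breaks the other clade: origins = a^b + d
        ann = annotate_ancestral_states(tree, m)
        assert parsimony_score(ann) == 2

    def test_missing_leaves_do_not_break_subtrees(self):
        tree = _balanced_tree(["a", "b", "c", "d"])
        m = CharacterMatrix([[7], [MISSING], [7], [7]], ["a", "b", "c", "d"])
        ann = annotate_ancestral_states(tree, m)
        assert parsimony_score(ann) == 1

    def test_star_tree_with_shared_mutation(self):
        g = nx.DiGraph()
        for leaf in "abcd":
            g.add_edge("root", leaf)
        tree = LineageTree(g, "root")
        m = CharacterMatrix([[3]] * 4, list("abcd"))
        ann = annotate_ancestral_states(tree, m)
        # under leaf-only annotation this would cost 4; minimal labeling: 1
        assert parsimony_score(ann) == 1

    def test_unmapped_leaf_raises(self):
        tree = _balanced_tree(["a", "b", "c", "d"])
        m = CharacterMatrix([[1]] * 3, ["a", "b", "c"])
        with pytest.raises(ValueError, match="no row"):
            annotate_ancestral_states(tree, m)

    def _exhaustive_min_parsimony(self, tree, matrix):
        """Brute-force minimum over all irreversible internal labelings."""
        internal = [v for v in tree.graph if tree.children(v)]
        chars = range(matrix.m)
        best_total = 0
        for j in chars:
            states = sorted({int(s) for s in matrix.values[:, j] if s > 0})
            best = None
            for labels in itertools.product([0] + states, repeat=len(internal)):
                lab = dict(zip(internal, labels))
                ok = True
                # a nonzero root label costs one origin on the founder edge
                cost = 1 if lab[tree.root] != 0 else 0
                for u, v in tree.graph.edges:
                    su = lab[u]
                    if tree.children(v):
                        sv = lab[v]
                    else:
                        sv = int(matrix.row(v)[j])
                        if sv == MISSING:
                            continue
                    if su != sv:
                        if su != 0:
                            ok = False
                            break
                        cost += 1
                if ok and (best is None or cost < best):
                    best = cost
            best_total += best
        return best_total

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_minimal_labeling(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(4, 7))
        leaves = [f"c{i}" for i in range(n_leaves)]
        tree = _balanced_tree(leaves)
        vals = rng.integers(0, 4, size=(n_leaves, 2))
        vals[rng.uniform(size=vals.shape) < 0.15] = MISSING
        m = CharacterMatrix(vals, leaves)
        ann = annotate_ancestral_states(tree, m)
        assert parsimony_score(ann) == self._exhaustive_min_parsimony(tree, m)


class TestTriplets:
    def test_identical_trees_score_one(self, perfect_experiment):
        rep = triplets_correct(perfect_experiment.tree,
                               perfect_experiment.tree,
                               n_triplets=500, seed=0)
        assert rep.thresholded == 1.0
        assert rep.unthresholded == 1.0

    def test_random_tree_scores_about_one_third(self, perfect_experiment):
        rng = np.random.default_rng(0)
        leaves = perfect_experiment.tree.leaves()
        shuffled = list(leaves)
        rng.shuffle(shuffled)
        random_tree = _balanced_tree(shuffled)
        rep = triplets_correct(perfect_experiment.tree, random_tree,
                               n_triplets=4000, seed=1)
        # resolved random triplets match with probability 1/3
        assert rep.unthresholded == pytest.approx(1 / 3, abs=0.08)

    def test_small_tree_falls_back_to_unthresholded(self):
        tree = _balanced_tree([f"c{i}" for i in range(16)])
        with pytest.warns(UserWarning, match="threshold"):
            rep = triplets_correct(tree, tree, n_triplets=200, min_cells=20,
                                   seed=0)
        assert rep.thresholded == rep.unthresholded

    def test_needs_three_shared_leaves(self):
        t1 = _balanced_tree(["a", "b"])
        with pytest.raises(ValueError):
            triplets_correct(t1, t1, seed=0)

    def test_fractions_within_unit_interval(self, default_experiment):
        recon = build_greedy(default_experiment.observed).tree
        rep = triplets_correct(default_experiment.tree, recon,
                               n_triplets=1000, seed=2)
        assert all(0 <= f <= 1 for f in rep.per_depth_correct.values())


class TestPurity:
    def _labeled_tree(self, n=8):
        leaves = [f"c{i}" for i in range(n)]
        tree = _balanced_tree(leaves)
        labels = {leaf: ("A" if i < n // 2 else "B")
                  for i, leaf in enumerate(leaves)}
        return tree, labels

    def test_perfect_separation_statistic_equals_n(self):
        tree, labels = self._labeled_tree(8)
        stat, clades = meta_purity(tree, labels, 2)
        assert clades == 2
        assert stat == pytest.approx(8.0)

    def test_identical_labels_give_zero(self):
        tree, _ = self._labeled_tree(8)
        labels = {leaf: "A" for leaf in tree.leaves()}
        stat, _ = meta_purity(tree, labels, 2)
        assert stat == 0.0

    def test_majority_vote_homogeneous(self):
        tree, labels = self._labeled_tree(8)
        assert mean_majority_vote(tree, labels, 2) == 1.0

    def test_majority_vote_even_split_is_half(self):
        tree, _ = self._labeled_tree(8)
        labels = {f"c{i}": ("A" if i % 2 == 0 else "B") for i in range(8)}
        assert mean_majority_vote(tree, labels, 4) == 0.5

    def test_majority_vote_three_one(self):
        g = nx.DiGraph()
        g.add_edge("root", "m")
        for leaf in "abcd":
            g.add_edge("m", leaf)
        g.add_edge("root", "e")
        tree = LineageTree(g, "root")
        labels = {"a": "A", "b": "A", "c": "A", "d": "B", "e": "B"}
        assert mean_majority_vote(tree, labels, 2) == pytest.approx(
            (0.75 + 1.0) / 2)

    def test_too_many_clades_requested(self):
        tree, labels = self._labeled_tree(4)
        with pytest.raises(ValueError, match="clades"):
            meta_purity(tree, labels, 50)


class TestDistances:
    def test_allelic_identical(self):
        assert allelic_distance([1, 2, 0], [1, 2, 0]) == 0.0

    def test_allelic_missing_counts_one(self):
        a = [3] + [0] * 9
        b = [MISSING] + [0] * 9
        assert allelic_distance(a, b) == pytest.approx(1 / 20)

    def test_allelic_two_nonzero_counts_two(self):
        a = [3] + [0] * 9
        b = [4] + [0] * 9
        assert allelic_distance(a, b) == pytest.approx(2 / 20)

    def _annotated_cherry(self):
        g = nx.DiGraph()
        g.add_node("root", state=(0, 0))
        g.add_node("a", state=(1, 0))
        g.add_node("b", state=(0, 2))
        g.add_edge("root", "a")
        g.add_edge("root", "b")
        tree = LineageTree(g, "root")
        tree.annotate_edges_from_states()
        return tree

    def test_phylogenetic_self_distance_zero(self):
        tree = self._annotated_cherry()
        assert phylogenetic_distance(tree, "a", "a") == 0.0

    def test_siblings_with_private_mutations(self):
        tree = self._annotated_cherry()
        assert phylogenetic_distance(tree, "a", "b", normalized=False) == 2.0
        assert phylogenetic_distance(tree, "a", "b") == 1.0  # diameter pair

    def test_diameter_positive(self, perfect_experiment):
        assert tree_diameter(perfect_experiment.tree) > 0


class TestBootstrap:
    def test_column_count_preserved(self, small_matrix):
        reps = bootstrap_characters(small_matrix, B=5, seed=0)
        assert len(reps) == 5
        assert all(r.m == small_matrix.m for r in reps)

    def test_reproducible_given_seed(self, small_matrix):
        a = bootstrap_characters(small_matrix, B=1, seed=3)[0]
        b = bootstrap_characters(small_matrix, B=1, seed=3)[0]
        assert (a.values == b.values).all()

    def test_distinct_column_fraction(self):
        m = CharacterMatrix(np.arange(200).reshape(2, 100))
        fracs = [len(set(r.characters)) / 100
                 for r in bootstrap_characters(m, B=200, seed=1)]
        expected = 1 - (1 - 1 / 100) ** 100
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)


class TestNeighborJoining:
    def test_dissimilarity_definition(self):
        m = CharacterMatrix([[1, 0], [2, 0], [1, 0]], ["a", "b", "c"])
        # binarized columns: (r0=1, r0=2); a=(1,0), b=(0,1), c=(1,0)
        dm = binary_identity_dissimilarity(m)
        assert dm[0, 1] == pytest.approx(1.0)
        assert dm[0, 2] == pytest.approx(0.0)

    def test_leaves_and_rooting(self, default_experiment):
        tree = neighbor_joining(default_experiment.observed)
        assert sorted(tree.leaves()) == \
            sorted(default_experiment.observed.cell_ids)
        assert tree.graph.in_degree(tree.root) == 0

    def test_recovers_clean_split(self):
        vals = np.zeros((6, 8), dtype=int)
        vals[:3, :4] = [[1] * 4] * 3
        vals[3:, 4:] = [[2] * 4] * 3
        vals[np.arange(6), np.arange(6) % 8] += np.arange(6)  # perturb
        m = CharacterMatrix(vals, [f"c{i}" for i in range(6)])
        tree = neighbor_joining(m)
        rep_leaves = {frozenset(
            x for x in (nx.descendants(tree.graph, child) | {child})
            if tree.graph.out_degree(x) == 0)
            for child in tree.children(tree.root)}
        # one side of the root split should be a subset of {c0,c1,c2} or
        # {c3,c4,c5}
        groups = [frozenset({"c0", "c1", "c2"}), frozenset({"c3", "c4", "c5"})]
        assert any(side <= g for side in rep_leaves for g in groups)
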