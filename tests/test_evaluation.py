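"""Rand index, random binary trees, and the t-calibrated null model."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from proteokmer.evaluation import (
    contingency_counts,
    critical_value_from_moments,
    null_rand_distribution,
    rand_index,
    random_binary_tree,
    significance_test,
)
from proteokmer.tree_flatten import FlatClustering, ReferenceClassification


def brute_force_rand(clustering: FlatClustering, ref: ReferenceClassification) -> float:
    items = sorted(clustering.assignments)
    agree = 0
    for a, b in itertools.combinations(items, 2):
        same_cluster = clustering.assignments[a] == clustering.assignments[b]
        same_class = ref.classes[a] == ref.classes[b]
        agree += same_cluster == same_class
    return agree / comb(len(items), 2)


class TestRandIndex:
    def test_identical_partitions_give_one(self):
        c = FlatClustering({"a": 0, "b": 0, "c": 1})
        ref = ReferenceClassification({"a": "X", "b": "X", "c": "Y"})
        assert rand_index(c, ref) == 1.0

    def test_worked_example(self):
        # clusters {1,2}|{3} vs classes {1,3}|{2}: one FP, one FN, one TN
        c = FlatClustering({"1": 0, "2": 0, "3": 1})
        ref = ReferenceClassification({"1": "X", "2": "Y", "3": "X"})
        counts = contingency_counts(c, ref)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (0, 1, 1, 1)
        assert rand_index(c, ref) == pytest.approx(1 / 3)

    def test_all_singletons_vs_one_class(self):
        c = FlatClustering({"a": 0, "b": 1, "c": 2})
        ref = ReferenceClassification(dict.fromkeys("abc", "X"))
        assert rand_index(c, ref) == 0.0

    def test_domain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rand_index(FlatClustering({"a": 0}), ReferenceClassification({"b": "X"}))

    def test_matches_brute_force_and_is_symmetric(self, rng):
        for _ in range(30):
            items = [f"i{j}" for j in range(12)]
            c = FlatClustering({i: int(rng.integers(4)) for i in items})
            ref_labels = {i: f"C{rng.integers(3)}" for i in items}
            ref = ReferenceClassification(ref_labels)
            got = rand_index(c, ref)
            assert got == pytest.approx(brute_force_rand(c, ref))
            # symmetry: swap the roles of the two partitions
            swapped = rand_index(
                FlatClustering({i: hash(v) for i, v in ref_labels.items()}),
                ReferenceClassification({i: str(v) for i, v in c.assignments.items()}),
            )
            assert got == pytest.approx(swapped)

    def test_contingency_identity(self, rng):
        for _ in range(20):
            items = [f"i{j}" for j in range(10)]
            c = FlatClustering({i: int(rng.integers(3)) for i in items})
            ref = ReferenceClassification({i: f"C{rng.integers(3)}" for i in items})
            counts = contingency_counts(c, ref)
            assert counts.total == comb(10, 2)


class TestRandomBinaryTree:
    def test_two_leaves(self):
        tree = random_binary_tree(["a", "b"], 0)
        assert tree.n_leaves == 2 and tree.heights.tolist() == [1.0]

    def test_deterministic_given_seed(self):
        t1 = random_binary_tree([f"l{i}" for i in range(10)], 42)
        t2 = random_binary_tree([f"l{i}" for i in range(10)], 42)
        assert np.array_equal(t1.merges, t2.merges)

    def test_three_leaf_topologies_uniform(self):
        """Uniform first-pair choice makes each labeled 3-leaf topology
        appear with frequency 1/3."""
        rng = np.random.default_rng(7)
        counts = {"ab": 0, "ac": 0, "bc": 0}
        n = 30_000
        for _ in range(n):
            tree = random_binary_tree(list("abc"), rng)
            first = tree.node_labels(3)  # first join
            counts["".join(sorted(first))] += 1
        for v in counts.values():
            assert v / n == pytest.approx(1 / 3, abs=0.01)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            random_binary_tree(["a"], 0)


class TestNullModel:
    def test_singleton_classes_give_all_ones(self):
        """With every item its own class, the optimal flattening splits
        everything and every pair is a true negative."""
        ref = ReferenceClassification({f"i{j}": f"C{j}" for j in range(8)})
        null = null_rand_distribution(ref, n_trees=100, rng_seed=0)
        assert np.all(null.samples == 1.0)

    def test_one_class_gives_all_ones(self):
        ref = ReferenceClassification({f"i{j}": "C" for j in range(8)})
        null = null_rand_distribution(ref, n_trees=100, rng_seed=0)
        assert np.all(null.samples == 1.0)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            null_rand_distribution(ReferenceClassification({"a": "X"}), n_trees=100)

    def test_mean_reproducible_across_seeds(self):
        """Across seeds, null means agree within ~±0.001 at 2000 trees for
        a small multi-class reference (standard-error bound)."""
        ref = ReferenceClassification(
            {f"i{j:02d}": f"C{j % 6}" for j in range(30)}
        )
        means = [
            null_rand_distribution(ref, n_trees=2000, rng_seed=s).mean
            for s in (1, 2)
        ]
        assert abs(means[0] - means[1]) < 0.002

    def test_t_fit_recovers_known_parameters(self):
        """MLE on 10,000 draws from a known location-scale t recovers loc
        within 1e-4, scale within 20%, df within a factor of 2."""
        rng = np.random.default_rng(12345)
        true_df, true_loc, true_scale = 8.0, 0.95, 0.0005
        samples = stats.t.rvs(true_df, true_loc, true_scale, size=10_000,
                              random_state=rng)
        df, loc, scale = stats.t.fit(samples)
        assert loc == pytest.approx(true_loc, abs=1e-4)
        assert scale == pytest.approx(true_scale, rel=0.2)
        assert true_df / 2 <= df <= true_df * 2


class TestSignificance:
    def _null(self):
        ref = ReferenceClassification({f"i{j:02d}": f"C{j % 5}" for j in range(25)})
        return null_rand_distribution(ref, n_trees=300, rng_seed=3)

    def test_boundary_is_not_significant(self):
        null = self._null()
        significant, _ = significance_test(null.critical_value, null)
        assert not significant

    def test_perfect_rand_is_significant(self):
        null = self._null()
        assert null.fitted_loc < 1 and null.fitted_scale > 0
        significant, p = significance_test(1.0, null)
        assert significant and p < 0.05

    def test_published_threshold_from_moments(self):
        """A location-scale t with df 8.14, mean 0.9544 and standard
        deviation 0.0003 puts its 95% right-tail critical value at 0.9549."""
        assert round(critical_value_from_moments(0.9544, 0.0003, 8.14, 0.05), 4) \
            == 0.9549
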