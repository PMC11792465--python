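"""Diversity metrics against hand counts and a branch-enumeration oracle."""

import numpy as np
import pytest

from foodtrace.diversity import (
    bray_curtis,
    faith_pd,
    jaccard_similarity,
    rarefy,
    unweighted_unifrac,
)
from foodtrace.io import CompoundTable, FeatureTable
from foodtrace.simulate import generate_tree


def brute_force_unifrac(table, tree):
    """Independent oracle: enumerate each branch's tip subset via the tree
    API and compute unique/union spanned length per sample pair."""
    presence = {
        s: {f for j, f in enumerate(table.feature_ids) if table.counts[i, j] > 0}
        for i, s in enumerate(table.sample_ids)
    }
    branches = []  # (length, tip set)
    for node in tree.root.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        branches.append((node.length, tips))
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i, si in enumerate(table.sample_ids):
        for j, sj in enumerate(table.sample_ids):
            if j <= i:
                continue
            unique = union = 0.0
            for length, tips in branches:
                in_i = bool(tips & presence[si])
                in_j = bool(tips & presence[sj])
                if in_i or in_j:
                    union += length
                if in_i != in_j:
                    unique += length
            out[i, j] = out[j, i] = unique / union if union else 0.0
    return out


class TestRarefy:
    def make_table(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(4, 12))
        counts[:, 0] += 60
        return FeatureTable([f"s{i}" for i in range(4)], [f"f{j}" for j in range(12)], counts)

    def test_row_sums_and_determinism(self):
        table = self.make_table()
        out = rarefy(table, 50, seed=3)
        assert (out.counts.sum(axis=1) == 50).all()
        assert (out.counts <= table.counts).all()
        again = rarefy(table, 50, seed=3)
        assert np.array_equal(out.counts, again.counts)

    def test_exact_depth_sample_unchanged(self):
        table = FeatureTable(["s1"], ["a", "b"], np.array([[3, 7]]))
        out = rarefy(table, 10, seed=0)
        assert np.array_equal(out.counts, table.counts)

    def test_shallow_sample_names_offender(self):
        table = FeatureTable(["deep", "shallow"], ["a"], np.array([[100], [5]]))
        with pytest.raises(ValueError, match="shallow"):
            rarefy(table, 50, seed=0)


class TestFaithPD:
    def test_hand_counted_values(self, quartet_tree, quartet_table):
        pd_vec = faith_pd(quartet_table, quartet_tree)
        assert pd_vec["s1"] == pytest.approx(3.0)  # A, B and their stem
        assert pd_vec["s2"] == pytest.approx(2.0)  # A plus stem to root
        assert pd_vec["s3"] == pytest.approx(6.0)  # saturation: total length

    def test_monotone_in_taxa(self):
        tree = generate_tree(12, seed=4)
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=12)
        base[0] = 1
        richer = base.copy()
        richer[np.argmin(base)] = 1
        table = FeatureTable(["a", "b"], tree.tip_names, np.vstack([base, richer]))
        pd_vec = faith_pd(table, tree)
        assert pd_vec["b"] >= pd_vec["a"]

    def test_unknown_tip_is_error(self, quartet_tree):
        table = FeatureTable(["s"], ["A", "Z"], np.array([[1, 1]]))
        with pytest.raises(ValueError, match="Z"):
            faith_pd(table, quartet_tree)


class TestUnweightedUnifrac:
    def test_hand_counted_values(self, quartet_tree):
        table = FeatureTable(
            ["ab", "a", "c"], ["A", "B", "C", "D"],
            np.array([[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0]]),
        )
        dm = unweighted_unifrac(table, quartet_tree)
        assert dm[("ab", "ab")] == 0.0
        assert dm[("a", "c")] == 1.0  # disjoint clades share nothing
        assert dm[("ab", "a")] == pytest.approx(1 / 3)  # unique B over union 3

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            n_tips = int(rng.integers(4, 17))
            tree = generate_tree(n_tips, seed=int(rng.integers(0, 2**31 - 1)))
            n_samples = int(rng.integers(2, 6))
            pres = rng.integers(0, 2, size=(n_samples, n_tips))
            pres[:, rng.integers(0, n_tips)] = 1  # no empty samples
            table = FeatureTable(
                [f"s{i}" for i in range(n_samples)], tree.tip_names, pres
            )
            dm = unweighted_unifrac(table, tree)
            oracle = brute_force_unifrac(table, tree)
            assert np.abs(dm.values - oracle).max() <= 1e-10

    def test_bounded_and_valid(self, quartet_tree, quartet_table):
        dm = unweighted_unifrac(quartet_table, quartet_tree)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()

    def test_zero_total_sample_is_error(self, quartet_tree):
        table = FeatureTable(["s", "empty"], ["A"], np.array([[1], [0]]))
        with pytest.raises(ValueError, match="empty"):
            unweighted_unifrac(table, quartet_tree)


class TestBrayCurtis:
    def test_hand_values(self):
        table = CompoundTable(
            ["i", "j", "k", "l"], ["c1", "c2"],
            np.array([[2.0, 2.0], [1.0, 3.0], [2.0, 0.0], [0.0, 2.0]]),
            {"c1": "lipid", "c2": "lipid"},
        )
        dm = bray_curtis(table)
        assert dm[("i", "j")] == pytest.approx(0.25)  # (1+1)/8
        assert dm[("k", "l")] == 1.0
        assert dm[("i", "i")] == 0.0

    def test_invariant_to_zero_column(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(1, 10, size=(5, 4))
        t1 = CompoundTable(
            [f"s{i}" for i in range(5)], [f"c{j}" for j in range(4)], areas,
            {f"c{j}": "aqueous" for j in range(4)},
        )
        t2 = CompoundTable(
            [f"s{i}" for i in range(5)], [f"c{j}" for j in range(5)],
            np.hstack([areas, np.zeros((5, 1))]),
            {f"c{j}": "aqueous" for j in range(5)},
        )
        assert np.allclose(bray_curtis(t1).values, bray_curtis(t2).values)

    def test_all_zero_sample_is_error(self):
        table = CompoundTable(
            ["s1", "s2"], ["c"], np.array([[1.0], [0.0]]), {"c": "lipid"}
        )
        with pytest.raises(ValueError, match="s2"):
            bray_curtis(table)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            (set(), set(), 1.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected
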