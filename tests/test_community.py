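"""PERMANOVA, centroid collapsing, averaging and BH adjustment."""

import itertools

import numpy as np
import pytest

from foodtrace.community import (
    bh_adjust,
    collapse_abundances,
    collapse_to_centroids,
    compound_composition_screen,
    permanova,
)
from foodtrace.diversity import DiversityVector
from foodtrace.io import CompoundTable, DistanceMatrix


def euclidean_dm(points, labels):
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    return DistanceMatrix(labels, d)


def permanova_f(dm_values, x):
    """Independent pseudo-F oracle via explicit hat-matrix algebra."""
    n = len(x)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dm_values**2) @ j
    X = np.column_stack([np.ones(n), x])
    h = X @ np.linalg.inv(X.T @ X) @ X.T
    ss_expl = np.trace(h @ g @ h)
    ss_res = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
    return (ss_expl / 1) / (ss_res / (n - 2))


class TestPermanova:
    def test_separable_groups(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
        dm = euclidean_dm(pts, [f"s{i}" for i in range(6)])
        res = permanova(dm, np.array(["a", "a", "a", "b", "b", "b"]), n_perm=999, seed=1)
        assert res.r_squared > 0.9
        # smallest achievable p for two groups of 3 is the tie fraction 72/720
        assert res.p_value == pytest.approx(0.1, abs=0.03)

    def test_continuous_f_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        dm = euclidean_dm(pts, [f"s{i}" for i in range(8)])
        x = rng.normal(size=8)
        res = permanova(dm, x, n_perm=9, seed=0)
        assert res.pseudo_F == pytest.approx(permanova_f(dm.values, x), abs=1e-10)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        dm = euclidean_dm(pts, [f"s{i}" for i in range(6)])
        x = rng.normal(size=6)
        f_obs = permanova_f(dm.values, x)
        hits = sum(
            permanova_f(dm.values, np.asarray(perm)) >= f_obs - 1e-12
            for perm in itertools.permutations(x)
        )
        exact_p = hits / 720
        res = permanova(dm, x, n_perm=4999, seed=9)
        mc_err = 3 * np.sqrt(exact_p * (1 - exact_p) / 4999)
        assert abs(res.p_value - exact_p) <= mc_err + 1e-3

    def test_constant_predictor_error(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)), list("abcde"))
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, np.ones(5), n_perm=9, seed=0)


class TestCentroidCollapse:
    def test_singleton_groups_identity(self):
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.normal(size=(4, 2)), list("abcd"))
        out = collapse_to_centroids(dm, {s: s for s in "abcd"})
        assert np.allclose(out.values, dm.values)

    def test_matches_coordinate_centroid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_groups = int(rng.integers(2, 5))
            sizes = rng.integers(1, 5, n_groups)
            pts, labels, groups = [], [], {}
            for gi, size in enumerate(sizes):
                for k in range(size):
                    labels.append(f"g{gi}_{k}")
                    groups[f"g{gi}_{k}"] = f"g{gi}"
                    pts.append(rng.normal(size=2))
            pts = np.array(pts)
            dm = euclidean_dm(pts, labels)
            out = collapse_to_centroids(dm, groups)
            centroids = np.array(
                [
                    pts[[i for i, lab in enumerate(labels) if groups[lab] == u]].mean(axis=0)
                    for u in out.labels
                ]
            )
            oracle = np.sqrt(((centroids[:, None] - centroids[None]) ** 2).sum(-1))
            assert np.abs(out.values - oracle).max() <= 1e-8

    def test_duplicated_points_collapse_to_point_distance(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        dm = euclidean_dm(pts, ["a1", "a2", "b1", "b2"])
        out = collapse_to_centroids(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert out[("A", "B")] == pytest.approx(5.0)

    def test_unassigned_sample_is_error(self):
        dm = euclidean_dm(np.zeros((3, 2)), list("abc"))
        with pytest.raises(ValueError, match="c"):
            collapse_to_centroids(dm, {"a": "g", "b": "g"})


class TestCollapseAbundances:
    def test_group_means_and_grand_mean(self):
        table = CompoundTable(
            ["s1", "s2", "s3", "s4"], ["c"],
            np.array([[2.0], [4.0], [1.0], [7.0]]), {"c": "lipid"},
        )
        groups = {"s1": "u1", "s2": "u1", "s3": "u2", "s4": "u2"}
        out = collapse_abundances(table, groups)
        assert out.areas[:, 0].tolist() == [3.0, 4.0]
        # equal-sized groups: mean of group means is the grand mean
        assert out.areas[:, 0].mean() == pytest.approx(table.areas[:, 0].mean())

    def test_diversity_vector(self):
        vec = DiversityVector(["s1", "s2"], np.array([2.0, 4.0]))
        out = collapse_abundances(vec, {"s1": "u", "s2": "u"})
        assert out.values.tolist() == [3.0]


class TestBH:
    def test_hand_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_equal_and_single(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        assert bh_adjust([0.7])[0] == pytest.approx(0.7)

    def test_never_decreases_and_keeps_minimum(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert np.argmin(adj) == np.argmin(p) or adj[np.argmin(p)] == adj.min()

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCompositionScreen:
    def test_planted_compound_ranks_first(self):
        rng = np.random.default_rng(12)
        n = 13
        driver = rng.normal(size=n)
        pts = np.column_stack([driver, 0.05 * rng.normal(size=n)])
        dm = euclidean_dm(pts, [f"u{i}" for i in range(n)])
        areas = np.column_stack(
            [driver - driver.min() + 1.0]
            + [rng.uniform(1, 2, size=n) for _ in range(5)]
        )
        table = CompoundTable(
            [f"u{i}" for i in range(n)],
            [f"c{j}" for j in range(6)],
            areas,
            {f"c{j}": "lipid" for j in range(6)},
        )
        rows = compound_composition_screen(dm, table, n_perm=499, seed=0)
        best = max(rows, key=lambda r: r.statistic)
        assert best.feature_id == "c0"

    def test_constant_compound_flagged_not_fatal(self):
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.normal(size=(6, 2)), [f"u{i}" for i in range(6)])
        table = CompoundTable(
            [f"u{i}" for i in range(6)], ["flat", "ok"],
            np.column_stack([np.ones(6), rng.uniform(1, 2, 6)]),
            {"flat": "lipid", "ok": "lipid"},
        )
        rows = compound_composition_screen(dm, table, n_perm=49, seed=0)
        flat = next(r for r in rows if r.feature_id == "flat")
        assert flat.excluded and "constant" in flat.exclusion_reason

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        dm = euclidean_dm(rng.normal(size=(7, 2)), [f"u{i}" for i in range(7)])
        table = CompoundTable(
            [f"u{i}" for i in range(7)], ["c1", "c2"],
            rng.uniform(1, 2, size=(7, 2)), {"c1": "lipid", "c2": "aqueous"},
        )
        r1 = compound_composition_screen(dm, table, n_perm=99, seed=3)
        r2 = compound_composition_screen(dm, table, n_perm=99, seed=3)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]
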