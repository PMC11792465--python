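"""Regression screens: sandwich variance, DFFITS, the REML random-intercept
model (including a frozen lme4/lmerTest cross-check), and screen behavior."""

import numpy as np
import pytest

from foodtrace.diversity import DiversityVector
from foodtrace.io import CompoundTable, FeatureTable, SampleMetadata
from foodtrace.regression import (
    arcsinh_percent,
    dffits,
    diversity_screen,
    lmm_influence,
    lmm_random_intercept,
    ols_cluster_robust,
    taxon_screen,
    zscore,
)


def sandwich_oracle(y, x, clusters):
    """Explicit block-sandwich CR1 variance, built from dense matrices."""
    X = np.column_stack([np.ones_like(x), x])
    n, k = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for lab in sorted(set(clusters)):
        sel = np.asarray(clusters) == lab
        s = X[sel].T @ u[sel]
        meat += np.outer(s, s)
    g = len(set(clusters))
    c = g / (g - 1) * (n - 1) / (n - k)
    return beta[1], c * (bread @ meat @ bread)[1, 1]


class TestTransforms:
    def test_zscore_values_and_idempotence(self):
        z = zscore([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1, 0, 1])
        assert np.allclose(zscore(z), z)

    def test_zscore_constant_error(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])

    def test_arcsinh_percent(self):
        assert arcsinh_percent(0.0) == 0.0
        assert arcsinh_percent(0.01) == pytest.approx(np.log(1 + np.sqrt(2)))
        grid = np.linspace(0, 1, 11)
        assert (np.diff(arcsinh_percent(grid)) > 0).all()
        with pytest.raises(ValueError):
            arcsinh_percent(1.5)


class TestClusterRobust:
    def test_perfect_fit_zero_se(self):
        x = np.arange(6.0)
        fit = ols_cluster_robust(2 * x + 1, x, [0, 0, 1, 1, 2, 2])
        assert fit.beta == pytest.approx(2.0)
        assert fit.se == pytest.approx(0.0, abs=1e-10)

    def test_matches_block_sandwich_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(6, 13))
            g = int(rng.integers(2, 5))
            clusters = rng.integers(0, g, n)
            clusters[:g] = np.arange(g)  # every cluster non-empty
            x = rng.normal(size=n)
            y = 0.7 * x + rng.normal(size=n)
            fit = ols_cluster_robust(y, x, clusters)
            beta, var = sandwich_oracle(y, x, clusters)
            assert fit.beta == pytest.approx(beta, abs=1e-10)
            assert fit.se**2 == pytest.approx(var, abs=1e-10)

    def test_singleton_clusters_reduce_to_hc1_scaled(self):
        rng = np.random.default_rng(1)
        n = 8
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        fit = ols_cluster_robust(y, x, np.arange(n))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        u = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = (X * u[:, None]).T @ (X * u[:, None])
        hc = (n / (n - 1)) * ((n - 1) / (n - 2)) * (bread @ meat @ bread)[1, 1]
        assert fit.se**2 == pytest.approx(hc, rel=1e-10)

    def test_single_cluster_error(self):
        with pytest.raises(ValueError):
            ols_cluster_robust([1.0, 2.0], [0.0, 1.0], ["a", "a"])


class TestDffits:
    def test_outlier_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 20.0])
        d = dffits(y, x)
        assert abs(d[-1]) > 1

    def test_perfect_line_all_zero(self):
        x = np.arange(5.0)
        assert np.allclose(dffits(3 * x + 2, x), 0.0)

    def test_matches_leave_one_out_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        y = 1.5 * x + rng.normal(size=10)
        d = dffits(y, x)
        X = np.column_stack([np.ones(10), x])
        h = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        for i in range(10):
            mask = np.ones(10, dtype=bool)
            mask[i] = False
            beta_i = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            resid_i = y[mask] - X[mask] @ beta_i
            s_i = np.sqrt(resid_i @ resid_i / (9 - 2))
            yhat_full = X[i] @ np.linalg.lstsq(X, y, rcond=None)[0]
            yhat_drop = X[i] @ beta_i
            oracle = (yhat_full - yhat_drop) / (s_i * np.sqrt(h[i]))
            assert d[i] == pytest.approx(oracle, abs=1e-10)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            dffits([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            dffits(np.arange(5.0), np.ones(5))


class TestLMM:
    def test_zero_unit_variance_reduces_to_ols(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=24)
        y = 0.8 * x + rng.normal(0, 0.5, 24)  # no unit effect at all
        units = np.repeat(np.arange(8), 3)
        fit = lmm_random_intercept(y, x, units)
        X = np.column_stack([np.ones(24), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        if fit.sigma_u2 == 0.0:
            assert fit.beta == pytest.approx(beta_ols, abs=1e-6)
            assert fit.df == 22
        else:  # tiny positive estimate still close to OLS
            assert fit.beta == pytest.approx(beta_ols, rel=0.05)

    def test_matches_lme4_lmertest_reference(self):
        """Frozen reference fit from R's lme4/lmerTest (REML, Satterthwaite)
        on this exact dataset: beta 0.30845560462, se 0.1669314038,
        df 14.665759997, p 0.08489959441."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        units = np.repeat(np.arange(10), 2)
        y = 0.5 * x + rng.normal(0, 0.5, 10)[units] + rng.normal(0, 0.5, 20)
        fit = lmm_random_intercept(y, x, units)
        assert fit.beta == pytest.approx(0.30845560462, abs=1e-6)
        assert fit.se == pytest.approx(0.1669314038, abs=1e-6)
        assert fit.df == pytest.approx(14.665759997, abs=1e-3)
        assert fit.p_value == pytest.approx(0.08489959441, abs=1e-4)

    def test_parameter_recovery_small(self):
        rng = np.random.default_rng(10)
        betas = []
        for _ in range(100):
            units = np.repeat(np.arange(10), 2)
            x = rng.normal(size=20)
            y = 0.5 * x + rng.normal(0, 0.5, 10)[units] + rng.normal(0, 0.5, 20)
            betas.append(lmm_random_intercept(y, x, units).beta)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.05)

    def test_too_few_units_error(self):
        with pytest.raises(ValueError):
            lmm_random_intercept(np.arange(4.0), np.arange(4.0), [0, 0, 1, 1])


def make_metadata(n_donors=10, reps=2, n_lcm=9):
    meta = []
    for d in range(n_donors):
        for r in range(reps):
            meta.append(
                SampleMetadata(f"hu{d}_{r}", "HU", f"D{d}", f"c{d % 3 + 1}")
            )
    for i in range(n_lcm):
        meta.append(SampleMetadata(f"lcm{i}", "LCM", None, f"c{i % 3 + 1}"))
    return meta


class TestDiversityScreen:
    def make_inputs(self, seed=0, planted_outlier=False):
        meta = make_metadata()
        ids = [m.sample_id for m in meta]
        rng = np.random.default_rng(seed)
        pd_vals = rng.uniform(3, 15, len(ids))
        signal = -1.0 * zscore(pd_vals) + rng.normal(0, 0.3, len(ids))
        noise = rng.normal(size=(len(ids), 3))
        areas = 1e5 + 1e4 * np.column_stack([signal, noise])
        if planted_outlier:
            areas[0, 1] = 5e6
        table = CompoundTable(
            ids, [f"c{j}" for j in range(4)], np.clip(areas, 0, None),
            {f"c{j}": "lipid" for j in range(4)},
        )
        return table, DiversityVector(ids, pd_vals), meta

    def test_planted_slope_recovered(self):
        table, pd_vec, meta = self.make_inputs()
        rows = diversity_screen(table, pd_vec, meta)
        planted = next(r for r in rows if r.feature_id == "c0")
        assert not planted.excluded
        assert planted.p_adjusted < 0.05
        expected = -1.0 / pd_vec.values.std(ddof=1)
        assert planted.effect_size == pytest.approx(expected, rel=0.2)

    def test_gross_outlier_excluded_by_dffits(self):
        table, pd_vec, meta = self.make_inputs(planted_outlier=True)
        rows = diversity_screen(table, pd_vec, meta)
        flagged = next(r for r in rows if r.feature_id == "c1")
        assert flagged.excluded
        assert "DFFITS" in flagged.exclusion_reason


class TestTaxonScreen:
    def make_world(self, seed=3):
        meta = make_metadata()
        ids = [m.sample_id for m in meta]
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 200, size=(len(ids), 5))
        counts[:, 0] += 50
        taxa = FeatureTable(ids, [f"t{j}" for j in range(5)], counts)
        rel = taxa.relative_abundances().to_numpy()
        x0 = arcsinh_percent(rel[:, 0])
        signal = 1.0 * zscore(x0) + rng.normal(0, 0.3, len(ids))
        areas = 1e5 + 1e4 * np.column_stack(
            [signal] + [rng.normal(size=len(ids)) for _ in range(2)]
        )
        compounds = CompoundTable(
            ids, ["planted", "n1", "n2"], np.clip(areas, 0, None),
            {c: "aqueous" for c in ["planted", "n1", "n2"]},
        )
        return compounds, taxa, meta

    def test_planted_pair_has_smallest_adjusted_p(self):
        compounds, taxa, meta = self.make_world()
        rows = taxon_screen(compounds, taxa, meta)
        ok = [r for r in rows if not r.excluded]
        best = min(ok, key=lambda r: (r.p_adjusted, r.p_value))
        assert best.extra["compound"] == "planted"
        assert best.extra["taxon"] == "t0"

    def test_influential_unit_excluded(self):
        compounds, taxa, meta = self.make_world()
        # plant a single influential unit: taxon t4 essentially private to one
        # sample whose compound n1 area also explodes, so deleting that
        # observation changes the slope estimate drastically
        taxa.counts[:, 4] = 0
        taxa.counts[0, 4] = 10_000
        taxa.counts[16, 4] = 5
        j = compounds.compound_ids.index("n1")
        compounds.areas[0, j] = 5e7
        rows = taxon_screen(compounds, taxa, meta)
        flagged = [
            r
            for r in rows
            if r.extra.get("compound") == "n1"
            and r.extra.get("taxon") == "t4"
            and r.excluded
        ]
        assert flagged  # dropped by the influence rule

    def test_hu_only_restricts_samples(self):
        compounds, taxa, meta = self.make_world()
        rows = taxon_screen(compounds, taxa, meta, hu_only=True)
        n_hu = sum(1 for m in meta if m.group == "HU")
        ok = [r for r in rows if not r.excluded]
        assert ok and all(r.extra["se"] >= 0 for r in ok)
        # refit a pair directly on the HU subset to confirm the restriction
        sub = [m.sample_id for m in meta if m.group == "HU"]
        assert len(sub) == n_hu


class TestInfluence:
    def test_leave_one_out_influence_detects_planted_point(self):
        rng = np.random.default_rng(9)
        units = np.repeat(np.arange(6), 3)
        x = rng.normal(size=18)
        y = 0.5 * x + rng.normal(0, 0.3, 18)
        y[0] += 50.0
        fit = lmm_random_intercept(y, x, units)
        infl = lmm_influence(y, x, units, fit)
        assert np.argmax(infl) == 0
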