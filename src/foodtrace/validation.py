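"""Self-benchmarks: oracle equivalence, permutation-test calibration and
parameter recovery on the emulated study design.

Each function here recomputes a headline property of the package from
scratch against an independent reference: a brute-force enumerator, an
explicit dense-matrix formula, exhaustive permutation, or the known ground
truth of the synthetic generator. The test suite asserts on these numbers
and the acceptance script reports them.
"""

from __future__ import annotations

import itertools

import numpy as np

from .balances import select_balance
from .community import collapse_to_centroids, permanova
from .diversity import faith_pd, rarefy, unweighted_unifrac
from .io import DistanceMatrix, FeatureTable
from .ordination import procrustes_randomization_test
from .regression import (
    dffits,
    diversity_screen,
    lmm_random_intercept,
    ols_cluster_robust,
)
from .simulate import SimConfig, generate_tree, generate_world
from .tracking import track

__all__ = [
    "unifrac_oracle_error",
    "centroid_oracle_error",
    "dffits_oracle_error",
    "cluster_se_oracle_error",
    "permanova_exhaustive_diff",
    "procrustes_type1_rate",
    "permanova_type1_rate",
    "lmm_recovery",
    "balance_recovery_rate",
    "diversity_screen_recovery",
    "tracking_recovery",
]


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------


def _brute_force_unifrac(table: FeatureTable, tree) -> np.ndarray:
    """Enumerate every branch's tip subset through the tree API and score
    unique/union spanned length per pair (independent of the bitmap path)."""
    presence = {
        s: {f for j, f in enumerate(table.feature_ids) if table.counts[i, j] > 0}
        for i, s in enumerate(table.sample_ids)
    }
    branches = []
    for node in tree.root.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        branches.append((node.length, tips))
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i, si in enumerate(table.sample_ids):
        for j in range(i + 1, n):
            sj = table.sample_ids[j]
            unique = union = 0.0
            for length, tips in branches:
                a, b = bool(tips & presence[si]), bool(tips & presence[sj])
                if a or b:
                    union += length
                if a != b:
                    unique += length
            out[i, j] = out[j, i] = unique / union if union else 0.0
    return out


def unifrac_oracle_error(n_instances: int = 50, seed: int = 0) -> float:
    """Max |implementation - brute force| over random tree/table instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_tips = int(rng.integers(4, 17))
        tree = generate_tree(n_tips, seed=int(rng.integers(0, 2**31 - 1)))
        n_samples = int(rng.integers(2, 6))
        pres = rng.integers(0, 2, size=(n_samples, n_tips))
        pres[:, rng.integers(0, n_tips)] = 1
        table = FeatureTable([f"s{i}" for i in range(n_samples)], tree.tip_names, pres)
        dm = unweighted_unifrac(table, tree)
        worst = max(worst, float(np.abs(dm.values - _brute_force_unifrac(table, tree)).max()))
    return worst


def centroid_oracle_error(n_instances: int = 50, seed: int = 0) -> float:
    """Max deviation of distance-only centroid collapsing from explicit
    coordinate-mean centroids on Euclidean inputs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_groups = int(rng.integers(2, 6))
        sizes = rng.integers(1, 5, n_groups)
        pts, labels, groups = [], [], {}
        for gi, size in enumerate(sizes):
            for k in range(size):
                lab = f"g{gi}_{k}"
                labels.append(lab)
                groups[lab] = f"g{gi}"
                pts.append(rng.normal(size=3))
        pts = np.array(pts)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        out = collapse_to_centroids(DistanceMatrix(labels, d), groups)
        centroids = np.array(
            [
                pts[[i for i, lab in enumerate(labels) if groups[lab] == u]].mean(axis=0)
                for u in out.labels
            ]
        )
        oracle = np.sqrt(((centroids[:, None] - centroids[None]) ** 2).sum(-1))
        worst = max(worst, float(np.abs(out.values - oracle).max()))
    return worst


def dffits_oracle_error(n_instances: int = 20, seed: int = 0) -> float:
    """Max deviation of DFFITS from brute-force leave-one-out refits."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(6, 15))
        x = rng.normal(size=n)
        y = 1.2 * x + rng.normal(size=n)
        d = dffits(y, x)
        X = np.column_stack([np.ones(n), x])
        h = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
        beta_full = np.linalg.lstsq(X, y, rcond=None)[0]
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            beta_i = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            resid_i = y[mask] - X[mask] @ beta_i
            s_i = np.sqrt(resid_i @ resid_i / (n - 1 - 2))
            oracle = (X[i] @ beta_full - X[i] @ beta_i) / (s_i * np.sqrt(h[i]))
            worst = max(worst, abs(float(d[i] - oracle)))
    return worst


def cluster_se_oracle_error(n_instances: int = 20, seed: int = 0) -> float:
    """Max deviation of the CR1 sandwich variance from the explicit dense
    block-sandwich formula on random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(6, 13))
        g = int(rng.integers(2, 5))
        clusters = rng.integers(0, g, n)
        clusters[:g] = np.arange(g)
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        fit = ols_cluster_robust(y, x, clusters)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        u = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((2, 2))
        for lab in range(g):
            sel = clusters == lab
            s = X[sel].T @ u[sel]
            meat += np.outer(s, s)
        c = g / (g - 1) * (n - 1) / (n - 2)
        var = (c * bread @ meat @ bread)[1, 1]
        worst = max(worst, abs(fit.se**2 - float(var)))
    return worst


def permanova_exhaustive_diff(seed: int = 0, n_perm: int = 4999) -> float:
    """|Monte-Carlo p - exhaustive-permutation p| at n = 6 (720 orderings)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(6, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
    x = rng.normal(size=6)

    def f_stat(xv):
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ (dm.values**2) @ j
        X = np.column_stack([np.ones(n), xv])
        h = X @ np.linalg.inv(X.T @ X) @ X.T
        ss_e = np.trace(h @ g @ h)
        ss_r = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
        return ss_e / (ss_r / (n - 2))

    f_obs = f_stat(x)
    hits = sum(
        f_stat(np.asarray(perm)) >= f_obs - 1e-12
        for perm in itertools.permutations(x)
    )
    exact_p = hits / 720
    mc_p = permanova(dm, x, n_perm=n_perm, seed=seed + 1).p_value
    return abs(mc_p - exact_p)


# ---------------------------------------------------------------------------
# Calibration under the null
# ---------------------------------------------------------------------------


def procrustes_type1_rate(
    n_rep: int = 200, n_perm: int = 999, n: int = 13, seed: int = 0
) -> float:
    """Fraction of null replicates (independent configurations) with
    randomization-test p <= 0.05."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        ref = rng.normal(size=(n, 3))
        tgt = rng.normal(size=(n, 3))
        res = procrustes_randomization_test(
            ref, tgt, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        hits += res.p_value <= 0.05
    return hits / n_rep


def permanova_type1_rate(
    n_rep: int = 200, n_perm: int = 999, n: int = 13, seed: int = 0
) -> float:
    """Type-I error of continuous-predictor PERMANOVA on null data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        x = rng.normal(size=n)
        res = permanova(dm, x, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)))
        hits += res.p_value <= 0.05
    return hits / n_rep


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def lmm_recovery(
    n_rep: int = 500,
    beta: float = 0.5,
    unit_sd: float = 0.5,
    resid_sd: float = 0.5,
    n_units: int = 10,
    reps: int = 2,
    seed: int = 0,
) -> dict:
    """Bias of the REML slope and coverage of its 95% Satterthwaite CI under
    the replicated-donor design."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    units = np.repeat(np.arange(n_units), reps)
    betas, covered = [], 0
    for _ in range(n_rep):
        x = rng.normal(size=n_units * reps)
        y = (
            beta * x
            + rng.normal(0, unit_sd, n_units)[units]
            + rng.normal(0, resid_sd, n_units * reps)
        )
        fit = lmm_random_intercept(y, x, units)
        betas.append(fit.beta)
        half = stats.t.ppf(0.975, fit.df) * fit.se
        covered += (fit.beta - half) <= beta <= (fit.beta + half)
    mean_beta = float(np.mean(betas))
    return {
        "mean_beta": mean_beta,
        "bias_pct": 100.0 * (mean_beta - beta) / beta,
        "ci_coverage": covered / n_rep,
        "n_rep": n_rep,
    }


def balance_recovery_rate(
    n_rep: int = 100, n: int = 13, n_taxa: int = 20, seed: int = 0
) -> float:
    """Fraction of replicates in which the greedy search returns exactly the
    planted two-taxon log-ratio."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    cols = [f"t{i:02d}" for i in range(n_taxa)]
    hits = 0
    for r in range(n_rep):
        comp = rng.dirichlet(np.ones(n_taxa) * 0.8, size=n)
        y = 2.0 * np.log(comp[:, 0] / comp[:, 1]) + rng.normal(0, 0.1, n)
        bal = select_balance(pd.DataFrame(comp, columns=cols), y, seed=r)
        hits += bal.numerator == ["t00"] and bal.denominator == ["t01"]
    return hits / n_rep


def diversity_screen_recovery(seed: int = 0) -> dict:
    """Run the full diversity screen on a default synthetic world and return
    the planted compounds' adjusted p-values and recovered slopes."""
    cfg = SimConfig(seed=seed)
    world = generate_world(cfg)
    rarefied = rarefy(world["feature_table"], cfg.depth_min, seed)
    pd_vec = faith_pd(rarefied, world["tree"])
    rows = diversity_screen(world["compound_table"], pd_vec, world["metadata"])
    by_id = {r.feature_id: r for r in rows}
    out = []
    for planted in world["ground_truth"].diversity_compounds:
        r = by_id[planted["compound"]]
        out.append(
            {
                "compound": planted["compound"],
                "excluded": r.excluded,
                "p_adjusted": r.p_adjusted,
                "slope": r.effect_size,
                "true_slope_per_pd_unit": planted["slope_per_pd_unit"],
            }
        )
    return {"planted": out}


def tracking_recovery(seed: int = 0) -> dict:
    """Recall / decoy acceptance / baseline accounting of the tracking
    cascade on a default synthetic world."""
    cfg = SimConfig(seed=seed)
    world = generate_world(cfg)
    truth = world["ground_truth"]
    report = track(
        list(world["lcms"]["extract"].values()),
        list(world["lcms"]["blanks"].values()),
        world["lcms"]["plasma"],
        world["lcms"]["baseline"],
    )
    retained = set(report.retained.compound_ids)
    true_ids = set(truth.true_compound_ids)
    recall = len(retained & true_ids) / len(true_ids)
    decoys = len(retained & set(truth.decoy_ids))
    return {
        "recall": recall,
        "decoy_acceptance": decoys,
        "baseline_removed": report.total_baseline_removed,
        "baseline_expected": len(truth.baseline_compounds),
        "report": report.to_dict(),
    }
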