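"""Compound-level regression screens.

Two screens relate plasma compound abundances to the microbiome:

* the diversity screen regresses the z-scored abundance of each compound on
  Faith's phylogenetic diversity with cluster-robust (CR1) standard errors,
  clustering on the treatment unit, and drops any regression containing a
  point with |DFFITS| > 1;
* the taxon screen fits, for every (compound, taxon) pair, the
  random-intercept model ``z(compound) ~ beta * arcsinh(100 * rel_abund)
  + (1 | treatment unit) + e`` by REML, tests beta with
  Satterthwaite-approximated degrees of freedom, and drops pairs whose
  maximum leave-one-observation-out influence on beta (standardized by
  se(beta), computed by refitting) reaches 4.

Both screens apply a Benjamini-Hochberg adjustment across the surviving
tests; per-feature failures are flagged rows, never aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .community import bh_adjust
from .diversity import DiversityVector
from .io import CompoundTable, FeatureTable, SampleMetadata, treatment_units
from .results import ScreenResult

logger = logging.getLogger("foodtrace")

__all__ = [
    "RegressionResult",
    "zscore",
    "arcsinh_percent",
    "ols_cluster_robust",
    "dffits",
    "diversity_screen",
    "lmm_random_intercept",
    "taxon_screen",
]


@dataclass
class RegressionResult:
    beta: float
    se: float
    df: float
    p_value: float
    n_used: int
    excluded: bool = False
    exclusion_reason: str | None = None
    sigma_u2: float | None = None  # random-intercept variance (LMM only)
    sigma_e2: float | None = None  # residual variance (LMM only)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if not self.excluded and not self.df > 0:
            raise ValueError("df must be positive for a usable fit")


def zscore(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample (ddof=1) standard deviation 1."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / x.std(ddof=1)


def arcsinh_percent(relative_abundance: float | np.ndarray) -> float | np.ndarray:
    """arcsinh of percent relative abundance: ln(y + sqrt(y^2 + 1)),
    y = 100 * input. Variance-stabilizing and exactly 0 at 0."""
    x = np.asarray(relative_abundance, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    out = np.arcsinh(100.0 * x)
    return float(out) if out.ndim == 0 else out


def _simple_design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


def ols_cluster_robust(
    y: Sequence[float] | np.ndarray,
    x: Sequence[float] | np.ndarray,
    clusters: Sequence,
) -> RegressionResult:
    """OLS slope with a CR1 cluster sandwich variance.

    The meat sums score outer products within clusters; the CR1 small-sample
    factor is G/(G-1) * (n-1)/(n-k); the t reference distribution has G-1 df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    clusters = np.asarray(clusters)
    if not (len(y) == len(x) == len(clusters)):
        raise ValueError("y, x and clusters must have equal length")
    labels = sorted(set(clusters.tolist()))
    g = len(labels)
    if g < 2:
        raise ValueError("cluster-robust errors need at least 2 clusters")
    X = _simple_design(x)
    n, k = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise ValueError("design is collinear (constant predictor)")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    meat = np.zeros((k, k))
    for lab in labels:
        idx = clusters == lab
        score = X[idx].T @ resid[idx]
        meat += np.outer(score, score)
    bread = np.linalg.inv(xtx)
    c = (g / (g - 1)) * ((n - 1) / (n - k))
    vcov = c * bread @ meat @ bread
    se = float(np.sqrt(max(vcov[1, 1], 0.0)))
    df = g - 1
    if se == 0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t = beta[1] / se
        p = float(2 * stats.t.sf(abs(t), df))
    return RegressionResult(
        beta=float(beta[1]), se=se, df=float(df), p_value=p, n_used=n
    )


def dffits(y: Sequence[float] | np.ndarray, x: Sequence[float] | np.ndarray) -> np.ndarray:
    """DFFITS per observation for the simple regression of y on x:
    e_i sqrt(h_i) / (s_(i) (1 - h_i)) with externally studentized scale."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("DFFITS needs at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("design is collinear (constant predictor)")
    X = _simple_design(x)
    k = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    beta = xtx_inv @ X.T @ y
    e = y - X @ beta
    sse = float(e @ e)
    if sse <= 1e-14 * (float(y @ y) + 1.0):  # numerically perfect fit
        return np.zeros(n)
    # externally studentized scale: s_(i)^2 = (SSE - e_i^2/(1-h_i)) / (n-k-1)
    s2_i = (sse - e**2 / (1 - h)) / (n - k - 1)
    s2_i = np.clip(s2_i, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = e * np.sqrt(h) / (np.sqrt(s2_i) * (1 - h))
    return np.where(np.isfinite(out), out, 0.0 if sse == 0 else np.inf)


def _align(
    compounds: CompoundTable, other_ids: Sequence[str]
) -> CompoundTable:
    if list(compounds.sample_ids) != list(other_ids):
        compounds = compounds.subset_samples(list(other_ids))
    return compounds


def diversity_screen(
    compounds: CompoundTable,
    pd_vector: DiversityVector,
    metadata: Sequence[SampleMetadata],
) -> list[ScreenResult]:
    """Per-compound regression of z-scored abundance on Faith's PD with
    cluster-robust errors; regressions with any |DFFITS| > 1 are excluded;
    BH across the survivors."""
    units = treatment_units(metadata)
    compounds = _align(compounds, pd_vector.sample_ids)
    clusters = [units[s] for s in compounds.sample_ids]
    x = pd_vector.values
    rows: list[ScreenResult] = []
    for j, cid in enumerate(compounds.compound_ids):
        try:
            yz = zscore(compounds.areas[:, j])
            d = dffits(yz, x)
            if np.any(np.abs(d) > 1):
                rows.append(
                    ScreenResult(
                        feature_id=cid,
                        statistic=None,
                        effect_size=None,
                        p_value=None,
                        excluded=True,
                        exclusion_reason="influential point: |DFFITS| > 1",
                    )
                )
                continue
            fit = ols_cluster_robust(yz, x, clusters)
            rows.append(
                ScreenResult(
                    feature_id=cid,
                    statistic=fit.beta / fit.se if fit.se > 0 else np.inf,
                    effect_size=fit.beta,
                    p_value=fit.p_value,
                    extra={"se": fit.se, "df": fit.df},
                )
            )
        except ValueError as exc:
            rows.append(
                ScreenResult(
                    feature_id=cid,
                    statistic=None,
                    effect_size=None,
                    p_value=None,
                    excluded=True,
                    exclusion_reason=str(exc),
                )
            )
    ok = [r for r in rows if not r.excluded]
    if ok:
        for r, a in zip(ok, bh_adjust([r.p_value for r in ok])):
            r.p_adjusted = float(a)
    return rows


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (REML, Satterthwaite df)
# ---------------------------------------------------------------------------


def _group_stats(x: np.ndarray, y: np.ndarray, gi: np.ndarray, g: int):
    """Sufficient statistics for the profiled REML criterion: full Gram of
    S = [1, x, y] and per-group column sums."""
    s = np.column_stack([np.ones_like(x), x, y])
    gram = s.T @ s
    gsums = np.vstack([np.bincount(gi, weights=s[:, c], minlength=g) for c in range(3)]).T
    gsizes = np.bincount(gi, minlength=g).astype(float)
    return gram, gsums, gsizes


def _profiled_pieces(lam: float, gram, gsums, gsizes, n: int):
    """A = X'V^-1 X, b = X'V^-1 y, yy = y'V^-1 y and log|V| at V = I + lam ZZ'."""
    w = lam / (1.0 + lam * gsizes)
    corr = (gsums * w[:, None]).T @ gsums  # sum_g w_g s_g s_g'
    m = gram - corr
    a = m[:2, :2]
    b = m[:2, 2]
    yy = m[2, 2]
    logdet_v = float(np.log1p(lam * gsizes).sum())
    return a, b, yy, logdet_v


def _reml_m2ll(lam: float, gram, gsums, gsizes, n: int) -> float:
    """-2 profiled REML log-likelihood (up to a constant) at variance ratio lam."""
    a, b, yy, logdet_v = _profiled_pieces(lam, gram, gsums, gsizes, n)
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(a, b)
    rss = max(yy - b @ beta, 1e-300)
    p = 2
    return logdet_v + logdet_a + (n - p) * np.log(rss / (n - p))


def lmm_random_intercept(
    y: Sequence[float] | np.ndarray,
    x: Sequence[float] | np.ndarray,
    unit: Sequence,
    compute_df: bool = True,
) -> RegressionResult:
    """REML fit of ``y = a + beta x + u_unit + e`` with one random intercept.

    The variance ratio lambda = sigma_u^2 / sigma_e^2 is profiled out and
    optimized on a log grid refined by bounded minimization; lambda = 0 (the
    OLS boundary) is always a candidate, in which case inference uses the OLS
    residual df. Otherwise the Wald t for beta uses Satterthwaite's df,
    computed from the numerical REML information of (sigma_u^2, sigma_e^2) by
    the delta method, with a flagged fallback to G - 1 on numerical failure.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    unit = np.asarray(unit)
    n = len(y)
    if not (len(x) == len(unit) == n):
        raise ValueError("y, x and unit must have equal length")
    labels, gi = np.unique(unit, return_inverse=True)
    g = len(labels)
    if g < 3:
        raise ValueError("random-intercept model needs >= 3 units")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    gram, gsums, gsizes = _group_stats(x, y, gi, g)

    obj = lambda t: _reml_m2ll(np.exp(t), gram, gsums, gsizes, n)
    grid = np.linspace(-10.0, 8.0, 25)
    vals = [obj(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        obj, bounds=(t0 - 1.5, t0 + 1.5), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    best = float(res.fun)
    converged = bool(np.isfinite(best))
    if _reml_m2ll(0.0, gram, gsums, gsizes, n) <= best + 1e-9:
        lam, best = 0.0, _reml_m2ll(0.0, gram, gsums, gsizes, n)

    a, b, yy, _ = _profiled_pieces(lam, gram, gsums, gsizes, n)
    beta_hat = np.linalg.solve(a, b)
    p = 2
    sigma_e2 = float(max(yy - b @ beta_hat, 0.0) / (n - p))
    sigma_u2 = lam * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(a)
    se = float(np.sqrt(max(cov_beta[1, 1], 0.0)))

    fallback = None
    if lam == 0.0 or not compute_df:
        df = float(n - p)
    else:
        df = _satterthwaite_df(
            np.array([sigma_u2, sigma_e2]), gram, gsums, gsizes, n
        )
        if not (np.isfinite(df) and df > 0):
            df = float(g - 1)
            fallback = "satterthwaite fallback to G-1"
            logger.debug("Satterthwaite df failed; using G-1")
    if se == 0:
        p_val = 0.0 if beta_hat[1] != 0 else 1.0
    else:
        p_val = float(2 * stats.t.sf(abs(beta_hat[1]) / se, df))
    return RegressionResult(
        beta=float(beta_hat[1]),
        se=se,
        df=float(df),
        p_value=p_val,
        n_used=n,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        converged=converged,
        exclusion_reason=fallback,
    )


def _slope_var(theta: np.ndarray, gram, gsums, gsizes, n: int) -> float:
    """Var(beta) as a function of theta = (sigma_u^2, sigma_e^2)."""
    su2, se2 = theta
    lam = su2 / se2
    a, _, _, _ = _profiled_pieces(lam, gram, gsums, gsizes, n)
    return float(se2 * np.linalg.inv(a)[1, 1])


def _reml_m2ll_theta(theta: np.ndarray, gram, gsums, gsizes, n: int) -> float:
    """-2 REML log-likelihood at unprofiled theta = (sigma_u^2, sigma_e^2)."""
    su2, se2 = theta
    if se2 <= 0 or su2 < 0:
        return np.inf
    lam = su2 / se2
    a, b, yy, logdet_v = _profiled_pieces(lam, gram, gsums, gsizes, n)
    sign, logdet_a = np.linalg.slogdet(a / se2)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(a, b)
    rss = max(yy - b @ beta, 1e-300)
    return n * np.log(se2) + logdet_v + logdet_a + rss / se2


def _satterthwaite_df(theta, gram, gsums, gsizes, n) -> float:
    """Delta-method Satterthwaite df: 2 C^2 / (grad' Var(theta) grad)."""
    try:
        h = 1e-5 * np.maximum(np.abs(theta), 1e-8)
        grad = np.zeros(2)
        for i in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] = max(tm[i] - h[i], 0.0)
            grad[i] = (
                _slope_var(tp, gram, gsums, gsizes, n)
                - _slope_var(tm, gram, gsums, gsizes, n)
            ) / (tp[i] - tm[i])
        hess = np.zeros((2, 2))
        f0 = _reml_m2ll_theta(theta, gram, gsums, gsizes, n)
        for i in range(2):
            for j in range(i, 2):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                val = (
                    _reml_m2ll_theta(tpp, gram, gsums, gsizes, n)
                    - _reml_m2ll_theta(tpm, gram, gsums, gsizes, n)
                    - _reml_m2ll_theta(tmp, gram, gsums, gsizes, n)
                    + _reml_m2ll_theta(tmm, gram, gsums, gsizes, n)
                ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        if not np.all(np.isfinite(hess)):
            return np.nan
        info = hess / 2.0  # observed REML information
        var_theta = np.linalg.inv(info)
        c = _slope_var(theta, gram, gsums, gsizes, n)
        denom = float(grad @ var_theta @ grad)
        if denom <= 0:
            return np.nan
        return 2.0 * c**2 / denom
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        return np.nan


def lmm_influence(
    y: np.ndarray, x: np.ndarray, unit: np.ndarray, fit: RegressionResult
) -> np.ndarray:
    """Leave-one-observation-out change in beta, standardized by se(beta),
    computed by exact refitting."""
    n = len(y)
    out = np.zeros(n)
    denom = fit.se if fit.se > 0 else 1.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            sub = lmm_random_intercept(y[mask], x[mask], unit[mask], compute_df=False)
            out[i] = abs(fit.beta - sub.beta) / denom
        except ValueError:
            out[i] = np.inf
    return out


def taxon_screen(
    compounds: CompoundTable,
    taxa: FeatureTable,
    metadata: Sequence[SampleMetadata],
    hu_only: bool = False,
    influence_threshold: float = 4.0,
) -> list[ScreenResult]:
    """Pairwise random-intercept screen of every (compound, taxon) pair.

    For each pair, ``z(compound) ~ arcsinh(100 * rel_abund) + (1 | unit)``;
    pairs whose maximum leave-one-out influence on beta reaches
    ``influence_threshold`` are excluded; BH across retained pairs.
    """
    meta = {m.sample_id: m for m in metadata}
    sample_ids = [s for s in taxa.sample_ids if not hu_only or meta[s].group == "HU"]
    if len(sample_ids) < 4:
        raise ValueError("too few samples for the taxon screen")
    units = np.array([meta[s].treatment_unit for s in sample_ids])
    tidx = [taxa.sample_ids.index(s) for s in sample_ids]
    rel = taxa.relative_abundances().to_numpy()[tidx, :]
    xmat = arcsinh_percent(rel)
    compounds = _align(compounds, sample_ids)
    rows: list[ScreenResult] = []
    for j, cid in enumerate(compounds.compound_ids):
        area = compounds.areas[:, j]
        for t, taxon in enumerate(taxa.feature_ids):
            pair = f"{cid}~{taxon}"
            x = xmat[:, t]
            try:
                yz = zscore(area)
                fit = lmm_random_intercept(yz, x, units)
                infl = lmm_influence(yz, x, units, fit)
                if np.max(infl) >= influence_threshold:
                    rows.append(
                        ScreenResult(
                            feature_id=pair,
                            statistic=None,
                            effect_size=None,
                            p_value=None,
                            excluded=True,
                            exclusion_reason=(
                                f"influential point: max influence "
                                f"{np.max(infl):.2f} >= {influence_threshold}"
                            ),
                            extra={"compound": cid, "taxon": taxon},
                        )
                    )
                    continue
                rows.append(
                    ScreenResult(
                        feature_id=pair,
                        statistic=fit.beta / fit.se if fit.se > 0 else np.inf,
                        effect_size=fit.beta,
                        p_value=fit.p_value,
                        extra={
                            "compound": cid,
                            "taxon": taxon,
                            "se": fit.se,
                            "df": fit.df,
                        },
                    )
                )
            except ValueError as exc:
                rows.append(
                    ScreenResult(
                        feature_id=pair,
                        statistic=None,
                        effect_size=None,
                        p_value=None,
                        excluded=True,
                        exclusion_reason=str(exc),
                        extra={"compound": cid, "taxon": taxon},
                    )
                )
    ok = [r for r in rows if not r.excluded]
    if ok:
        for r, a in zip(ok, bh_adjust([r.p_value for r in ok])):
            r.p_adjusted = float(a)
    return rows
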