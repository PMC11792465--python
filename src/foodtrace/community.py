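"""Distance-based community statistics.

PERMANOVA (McArdle-Anderson trace partition of the Gower-centered matrix,
supporting categorical and continuous predictors), collapsing of a distance
matrix to per-group centroids using the distance-only identity (no
coordinates needed), within-group arithmetic averaging of abundances, the
Benjamini-Hochberg step-up adjustment, and the per-compound composition
screen that runs one continuous-predictor PERMANOVA per compound against the
microbiome distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .diversity import DiversityVector
from .io import CompoundTable, DistanceMatrix
from .results import ScreenResult

logger = logging.getLogger("foodtrace")

__all__ = [
    "PermanovaResult",
    "permanova",
    "collapse_to_centroids",
    "collapse_abundances",
    "bh_adjust",
    "compound_composition_screen",
]


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if self.pseudo_F < 0:
            raise ValueError("pseudo_F must be non-negative")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared out of [0, 1]")


def _gower_center(dm_values: np.ndarray) -> np.ndarray:
    n = dm_values.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (dm_values**2) @ j


def _design(predictor: np.ndarray) -> tuple[np.ndarray, int]:
    """Design columns (without intercept) and df for a predictor vector."""
    if predictor.dtype.kind in "OUS" or predictor.dtype == bool:
        levels = sorted(set(predictor.tolist()))
        if len(levels) < 2:
            raise ValueError("categorical predictor needs >= 2 levels")
        cols = np.column_stack(
            [(predictor == lev).astype(float) for lev in levels[1:]]
        )
        return cols, len(levels) - 1
    x = predictor.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    return x.reshape(-1, 1), 1


def _explained_trace(g: np.ndarray, cols: np.ndarray) -> float:
    """tr(HGH) for the design (intercept + cols); G is already centered so
    the intercept's contribution vanishes and centering cols suffices."""
    xc = cols - cols.mean(axis=0)
    q, _ = np.linalg.qr(xc)
    return float(np.einsum("ij,jk,ki->", q.T, g, q))


def permanova(
    dm: DistanceMatrix,
    predictor: Sequence | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA for one predictor.

    Continuous predictors are centered and contribute one df; categorical
    predictors are dummy-coded. The permutation scheme shuffles predictor
    rows without restriction (the screens feed centroid-collapsed units, so
    observations are exchangeable).
    """
    predictor = np.asarray(predictor)
    n = len(dm)
    if predictor.shape[0] != n:
        raise ValueError("predictor length does not match distance matrix")
    cols, q = _design(predictor)
    if n - q - 1 <= 0:
        raise ValueError("not enough samples for the design")
    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))
    ss_expl = _explained_trace(g, cols)
    ss_res = ss_total - ss_expl
    f_obs = (ss_expl / q) / (ss_res / (n - q - 1))
    r2 = ss_expl / ss_total if ss_total > 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_e = _explained_trace(g, cols[perm])
        f_perm = (ss_e / q) / ((ss_total - ss_e) / (n - q - 1))
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs), r_squared=float(r2), p_value=p, n_permutations=n_perm
    )


def collapse_to_centroids(
    dm: DistanceMatrix, groups: Mapping[str, str]
) -> DistanceMatrix:
    """Collapse a distance matrix to between-group centroid distances.

    Uses the distance-only identity
    ``d^2(C_A, C_B) = mean(d^2(a, b)) - mean(d^2(a, a')) / 2
    - mean(d^2(b, b')) / 2``
    which equals the Euclidean distance between coordinate centroids whenever
    the input is Euclidean-embeddable. Negative squared distances arising from
    non-Euclidean input (e.g. unweighted UniFrac) are clipped to 0 with a
    warning.
    """
    missing = [s for s in dm.labels if s not in groups]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    unit_order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, s in enumerate(dm.labels):
        u = groups[s]
        if u not in members:
            members[u] = []
            unit_order.append(u)
        members[u].append(i)
    if any(len(v) == 0 for v in members.values()):
        raise ValueError("empty group")
    d2 = dm.values**2
    k = len(unit_order)
    out = np.zeros((k, k))
    self_term = {
        u: d2[np.ix_(idx, idx)].sum() / (2 * len(idx) ** 2)
        for u, idx in members.items()
    }
    clipped = False
    for a in range(k):
        ia = members[unit_order[a]]
        for b in range(a + 1, k):
            ib = members[unit_order[b]]
            cross = d2[np.ix_(ia, ib)].sum() / (len(ia) * len(ib))
            val = cross - self_term[unit_order[a]] - self_term[unit_order[b]]
            if val < 0:
                clipped = True
                val = 0.0
            out[a, b] = out[b, a] = np.sqrt(val)
    if clipped:
        logger.warning(
            "negative squared centroid distances clipped to 0 "
            "(non-Euclidean input)"
        )
    return DistanceMatrix(unit_order, out)


def collapse_abundances(
    data: CompoundTable | DiversityVector, groups: Mapping[str, str]
):
    """Arithmetic per-group means of a compound table or diversity vector;
    group order follows first appearance in the sample order."""
    sample_ids = data.sample_ids
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    unit_order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        u = groups[s]
        if u not in members:
            members[u] = []
            unit_order.append(u)
        members[u].append(i)
    if isinstance(data, DiversityVector):
        vals = np.array([data.values[members[u]].mean() for u in unit_order])
        return DiversityVector(unit_order, vals)
    areas = np.vstack([data.areas[members[u]].mean(axis=0) for u in unit_order])
    return CompoundTable(
        sample_ids=unit_order,
        compound_ids=list(data.compound_ids),
        areas=areas,
        fractions=dict(data.fractions),
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compound_composition_screen(
    dm_centroids: DistanceMatrix,
    compounds_centroids: CompoundTable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[ScreenResult]:
    """Per-compound PERMANOVA of the microbiome distance matrix on that
    compound's (centroid-averaged) abundance as a continuous predictor, with
    BH adjustment across compounds.

    Per-compound failures (e.g. a constant abundance vector) become excluded
    rows rather than aborting the screen. Raw p < 0.05 and adjusted p < 0.05
    are flagged separately in ``extra``.
    """
    if list(dm_centroids.labels) != list(compounds_centroids.sample_ids):
        compounds_centroids = compounds_centroids.subset_samples(dm_centroids.labels)
    rng = np.random.default_rng(seed)
    rows: list[ScreenResult] = []
    for j, cid in enumerate(compounds_centroids.compound_ids):
        x = compounds_centroids.areas[:, j]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = permanova(dm_centroids, x, n_perm=n_perm, seed=sub_seed)
            rows.append(
                ScreenResult(
                    feature_id=cid,
                    statistic=res.pseudo_F,
                    effect_size=res.r_squared,
                    p_value=res.p_value,
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
        adj = bh_adjust([r.p_value for r in ok])
        for r, a in zip(ok, adj):
            r.p_adjusted = float(a)
            r.extra["raw_significant"] = bool(r.p_value < 0.05)
            r.extra["adjusted_significant"] = bool(a < 0.05)
    return rows
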