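"""Selbal-style search for a log-ratio balance of taxa explaining a response.

A balance over disjoint taxon sets NUM (size p) and DEN (size q) is the
normalized log-contrast

    B = sqrt(p q / (p + q)) * (mean_i in NUM ln x_i - mean_j in DEN ln x_j)

computed on relative abundances with a pseudocount for zeros. The search is
greedy: score all singleton (num, den) pairs by the R^2 of a linear
regression of the response on the balance, then forward-add the single taxon
(to either side) that most improves R^2, until ``max_size`` taxa or no
improvement. Cross-validated R^2 repeats the whole selection inside each
training fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable

__all__ = ["Balance", "balance_value", "select_balance"]


@dataclass
class Balance:
    numerator: list[str]
    denominator: list[str]
    coefficient: float
    intercept: float
    r_squared: float
    cv_r_squared: float | None = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if set(self.numerator) & set(self.denominator):
            raise ValueError("numerator and denominator overlap")
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator must be non-empty")


def balance_value(
    composition: Mapping[str, float] | pd.Series,
    num: Sequence[str],
    den: Sequence[str],
    pseudocount: float = 0.0,
) -> float:
    """Balance score of one composition for the given numerator/denominator."""
    num, den = list(num), list(den)
    if set(num) & set(den):
        raise ValueError("numerator and denominator overlap")
    comp = pd.Series(composition, dtype=float)
    missing = [t for t in num + den if t not in comp.index]
    if missing:
        raise ValueError(f"taxa absent from composition: {missing}")
    p, q = len(num), len(den)
    coef = np.sqrt(p * q / (p + q))
    ln = np.log(comp + pseudocount)
    return float(coef * (ln[num].mean() - ln[den].mean()))


def _balance_matrix(
    logs: np.ndarray, col_pos: dict[str, int], num: Sequence[str], den: Sequence[str]
) -> np.ndarray:
    p, q = len(num), len(den)
    coef = np.sqrt(p * q / (p + q))
    ni = [col_pos[t] for t in num]
    di = [col_pos[t] for t in den]
    return coef * (logs[:, ni].mean(axis=1) - logs[:, di].mean(axis=1))


def _fit_r2(b: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, R^2) of y ~ b; R^2 = 0 for a degenerate balance."""
    vb = b.var()
    if vb == 0:
        return 0.0, float(y.mean()), 0.0
    slope = np.cov(b, y, ddof=1)[0, 1] / b.var(ddof=1)
    intercept = float(y.mean() - slope * b.mean())
    resid = y - (intercept + slope * b)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else 0.0
    return float(slope), intercept, float(r2)


def _best_pair(logs: np.ndarray, y: np.ndarray, taxa: list[str]) -> tuple[str, str, float]:
    """Best singleton (num, den) pair by R^2, oriented so the regression
    slope is positive; ties resolved lexicographically."""
    lc = logs - logs.mean(axis=0)
    yc = y - y.mean()
    n = len(y)
    cov_ly = lc.T @ yc / (n - 1)
    gram = lc.T @ lc / (n - 1)
    v = np.diag(gram)
    var_y = float(yc @ yc / (n - 1))
    p = logs.shape[1]
    best: tuple[float, str, str] | None = None
    for i in range(p):
        for j in range(i + 1, p):
            var_b = v[i] + v[j] - 2 * gram[i, j]
            if var_b <= 1e-300 or var_y == 0:
                continue
            cov_b = cov_ly[i] - cov_ly[j]
            r2 = cov_b**2 / (var_b * var_y)
            # orient so the slope (sign of cov_b with num = taxa[i]) is >= 0
            num, den = (taxa[i], taxa[j]) if cov_b >= 0 else (taxa[j], taxa[i])
            key = (-r2, num, den)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (r2, num, den)
    if best is None:
        raise ValueError("no informative taxon pair found")
    return best[1], best[2], best[0]


def _greedy_select(
    logs: np.ndarray, y: np.ndarray, taxa: list[str], max_size: int
) -> tuple[list[str], list[str]]:
    col_pos = {t: i for i, t in enumerate(taxa)}
    num_t, den_t, r2 = _best_pair(logs, y, taxa)
    num, den = [num_t], [den_t]
    while len(num) + len(den) < max_size:
        remaining = sorted(set(taxa) - set(num) - set(den))
        best: tuple[float, str, str] | None = None
        for cand in remaining:
            for side in ("num", "den"):
                trial_num = num + [cand] if side == "num" else num
                trial_den = den + [cand] if side == "den" else den
                b = _balance_matrix(logs, col_pos, trial_num, trial_den)
                _, _, trial_r2 = _fit_r2(b, y)
                key = (-trial_r2, cand, side)
                if best is None or key < (-best[0], best[1], best[2]):
                    best = (trial_r2, cand, side)
        if best is None or best[0] <= r2 + 1e-10:
            break
        r2 = best[0]
        if best[2] == "num":
            num.append(best[1])
        else:
            den.append(best[1])
    return num, den


def _relative_abundance_frame(taxa: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(taxa, FeatureTable):
        return taxa.relative_abundances()
    return taxa.astype(float)


def select_balance(
    taxa: FeatureTable | pd.DataFrame,
    response: Sequence[float] | np.ndarray,
    n_folds: int = 10,
    max_size: int = 8,
    seed: int = 0,
    pseudocount: float | None = None,
) -> Balance:
    """Greedy balance search with cross-validated R^2.

    ``pseudocount`` defaults to half the smallest nonzero relative abundance
    in the table. With fewer than 2 * ``n_folds`` samples, cross-validation
    degenerates to leave-one-out; otherwise folds are a seeded shuffle split.
    The final balance is refit on all data.
    """
    rel = _relative_abundance_frame(taxa)
    y = np.asarray(response, dtype=float)
    if rel.shape[1] < 2:
        raise ValueError("balance selection needs at least 2 taxa")
    if len(y) != rel.shape[0]:
        raise ValueError("response length does not match table")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    values = rel.to_numpy()
    if pseudocount is None:
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("all-zero composition table")
        pseudocount = float(nonzero.min() / 2.0)
    logs = np.log(values + pseudocount)
    taxa_ids = list(rel.columns)
    col_pos = {t: i for i, t in enumerate(taxa_ids)}

    num, den = _greedy_select(logs, y, taxa_ids, max_size)
    b = _balance_matrix(logs, col_pos, num, den)
    slope, intercept, r2 = _fit_r2(b, y)

    n = len(y)
    rng = np.random.default_rng(seed)
    if n < 2 * n_folds:
        folds = [np.array([i]) for i in range(n)]
    else:
        order = rng.permutation(n)
        folds = [np.sort(chunk) for chunk in np.array_split(order, n_folds)]
    press = 0.0
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        try:
            tr_num, tr_den = _greedy_select(logs[mask], y[mask], taxa_ids, max_size)
            bt = _balance_matrix(logs[mask], col_pos, tr_num, tr_den)
            sl, ic, _ = _fit_r2(bt, y[mask])
            bte = _balance_matrix(logs[test_idx], col_pos, tr_num, tr_den)
            press += float(((y[test_idx] - (ic + sl * bte)) ** 2).sum())
        except ValueError:
            press += float(((y[test_idx] - y[mask].mean()) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    cv_r2 = 1.0 - press / sst if sst > 0 else 0.0
    return Balance(
        numerator=num,
        denominator=den,
        coefficient=slope,
        intercept=intercept,
        r_squared=r2,
        cv_r_squared=float(cv_r2),
        pseudocount=pseudocount,
    )
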