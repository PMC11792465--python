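"""Principal coordinates analysis and Procrustes superimposition with the
m^2 (Gower) randomization test.

PCoA eigendecomposes the Gower-centered squared-distance matrix
``-1/2 J D^2 J``; axes with negative eigenvalues (non-Euclidean distance
input) are dropped and their total magnitude reported. Procrustes removes
translation, global scale and orthogonal rotation (reflections allowed) and
reports the minimized residual sum of squares m^2 in [0, 1] under the
unit-sum-of-squares scaling convention. The randomization test permutes the
row order of the target configuration and counts permuted fits at least as
good as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "ProcrustesResult",
    "pcoa",
    "procrustes",
    "procrustes_randomization_test",
]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray  # positive, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_magnitude: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")
        if self.proportion_explained.sum() > 1 + 1e-9:
            raise ValueError("proportion_explained sums above 1")


@dataclass
class ProcrustesResult:
    m_squared: float
    transformed_target: np.ndarray
    p_value: float | None = None
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.m_squared <= 1 + 1e-9:
            raise ValueError(f"m_squared out of [0, 1]: {self.m_squared}")
        self.m_squared = float(min(max(self.m_squared, 0.0), 1.0))


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-9) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix."""
    n = len(dm)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0)
    pos = vals > eig_tol * scale
    neg_mag = float(-vals[vals < -eig_tol * scale].sum())
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    denom = vals[pos].sum() + neg_mag
    prop = vals[pos] / denom if denom > 0 else vals[pos]
    return OrdinationResult(
        sample_ids=list(dm.labels),
        coordinates=coords,
        eigenvalues=vals[pos],
        proportion_explained=prop,
        negative_eigenvalue_magnitude=neg_mag,
    )


def _normalize(x: np.ndarray) -> np.ndarray:
    """Center to the origin and scale to unit sum of squares."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)
    ss = np.sqrt((x**2).sum())
    if ss == 0:
        raise ValueError("degenerate configuration: all points identical")
    return x / ss


def _pad_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = max(a.shape[1], b.shape[1])
    pa = np.zeros((a.shape[0], k))
    pb = np.zeros((b.shape[0], k))
    pa[:, : a.shape[1]] = a
    pb[:, : b.shape[1]] = b
    return pa, pb


def _m_squared(ref_norm: np.ndarray, tgt_norm: np.ndarray) -> float:
    # after unit scaling, min residual = 1 - (sum of singular values)^2
    s = np.linalg.svd(ref_norm.T @ tgt_norm, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes(
    reference: np.ndarray,
    target: np.ndarray,
    reference_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> ProcrustesResult:
    """Least-squares superimposition of ``target`` onto ``reference``.

    Rows must be aligned (same sample in the same row); when id lists are
    given they are checked for identity. Column counts may differ; the
    narrower configuration is zero-padded.
    """
    if reference_ids is not None and target_ids is not None:
        if list(reference_ids) != list(target_ids):
            raise ValueError("reference and target sample labels differ")
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if reference.shape[0] != target.shape[0]:
        raise ValueError("configurations have different numbers of rows")
    ref, tgt = _pad_columns(reference, target)
    ref_n, tgt_n = _normalize(ref), _normalize(tgt)
    u, s, vt = np.linalg.svd(ref_n.T @ tgt_n)
    rot = (u @ vt).T
    scale = s.sum()
    transformed = scale * tgt_n @ rot
    m2 = float(max(0.0, 1.0 - scale**2))
    return ProcrustesResult(m_squared=m2, transformed_target=transformed)


def procrustes_randomization_test(
    reference: np.ndarray,
    target: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    reference_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> ProcrustesResult:
    """PROTEST-style significance for the Procrustes fit.

    Permutes the target's row order ``n_perm`` times; the p-value is the
    add-one-corrected fraction of permutations with m^2 less than or equal to
    the observed m^2 (a better-or-equal fit counts against the null).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = procrustes(reference, target, reference_ids, target_ids)
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    ref, tgt = _pad_columns(reference, target)
    ref_n, tgt_n = _normalize(ref), _normalize(tgt)
    rng = np.random.default_rng(seed)
    n = ref_n.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # row permutation preserves centering and scale, so no renormalization
        if _m_squared(ref_n, tgt_n[perm]) <= observed.m_squared:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProcrustesResult(
        m_squared=observed.m_squared,
        transformed_target=observed.transformed_target,
        p_value=p,
        n_permutations=n_perm,
    )
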