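"""Alpha and beta diversity: rarefaction, Faith's PD, unweighted UniFrac,
Bray-Curtis, and Jaccard similarity.

Phylogenetic metrics use the rooted-spanning convention: a community spans
every branch whose subtree contains at least one of its present tips,
including the stems connecting the community's clades to the root. Faith's PD
is the summed length of that spanned set; unweighted UniFrac between two
communities is the length spanned by exactly one of them divided by the
length spanned by their union. Using the same convention in both keeps PD and
UniFrac mutually consistent.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .io import CompoundTable, DistanceMatrix, FeatureTable, Tree

logger = logging.getLogger("foodtrace")

__all__ = [
    "DiversityVector",
    "rarefy",
    "faith_pd",
    "unweighted_unifrac",
    "bray_curtis",
    "jaccard_similarity",
]


class DiversityVector:
    """Per-sample alpha-diversity values (Faith PD units: summed branch length)."""

    def __init__(self, sample_ids: Sequence[str], values: np.ndarray):
        self.sample_ids = [str(s) for s in sample_ids]
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("values length does not match sample ids")
        if (self.values < 0).any():
            raise ValueError("diversity values must be non-negative")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.values[self.sample_ids.index(sample_id)])

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.sample_ids)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples are processed in label order with a single generator, so the
    output is deterministic given the seed. A sample with fewer reads than
    ``depth`` is an error (the study picked the largest depth excluding no
    sample, so shortfall signals a misconfigured depth).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.counts.sum(axis=1)
    short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if short:
        raise ValueError(f"samples below rarefaction depth {depth}: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(len(table.sample_ids)):
        row = table.counts[i]
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    return FeatureTable(list(table.sample_ids), list(table.feature_ids), out)


def _presence_by_branch(table: FeatureTable, tree: Tree) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, spanned) where spanned[b, i] marks branch b in sample i's set."""
    present_features = [
        f for j, f in enumerate(table.feature_ids) if table.counts[:, j].any()
    ]
    missing = sorted(set(present_features) - set(tree.tip_names))
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    lengths, members = tree.branch_index()
    tip_pos = {name: i for i, name in enumerate(tree.tip_names)}
    # presence matrix over tree tip ordering
    pres = np.zeros((len(table.sample_ids), tree.n_tips), dtype=bool)
    for j, f in enumerate(table.feature_ids):
        if f in tip_pos:
            pres[:, tip_pos[f]] = table.counts[:, j] > 0
    spanned = members @ pres.T.astype(np.int64) > 0  # (n_branches, n_samples)
    return lengths, spanned


def faith_pd(table: FeatureTable, tree: Tree) -> DiversityVector:
    """Faith's phylogenetic diversity: total branch length of the minimal
    rooted subtree spanning each sample's present tips."""
    lengths, spanned = _presence_by_branch(table, tree)
    values = lengths @ spanned
    return DiversityVector(table.sample_ids, values)


def unweighted_unifrac(table: FeatureTable, tree: Tree) -> DistanceMatrix:
    """Unweighted UniFrac: unshared spanned branch length over union spanned
    branch length, for every sample pair."""
    zero = [s for s, t in zip(table.sample_ids, table.counts.sum(axis=1)) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    lengths, spanned = _presence_by_branch(table, tree)
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = spanned[:, i], spanned[:, j]
            union = float(lengths[a | b].sum())
            unique = float(lengths[a ^ b].sum())
            d[i, j] = d[j, i] = unique / union if union > 0 else 0.0
    return DistanceMatrix(table.sample_ids, d)


def bray_curtis(table: CompoundTable | FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on raw abundances:
    d(i, j) = sum |x_i - x_j| / sum (x_i + x_j)."""
    values = table.areas if isinstance(table, CompoundTable) else table.counts
    values = np.asarray(values, dtype=float)
    zero = [s for s, t in zip(table.sample_ids, values.sum(axis=1)) if t == 0]
    if zero:
        raise ValueError(f"all-zero samples: {zero}")
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(values[i] - values[i + 1 :]).sum(axis=1)
        tot = (values[i] + values[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff / tot
    d = d + d.T
    return DistanceMatrix(table.sample_ids, d)


def jaccard_similarity(a: set, b: set) -> float:
    """|a intersect b| / |a union b|; two empty sets count as identical (1)."""
    union = a | b
    if not union:
        logger.info("jaccard_similarity of two empty sets: returning 1 by convention")
        return 1.0
    return len(a & b) / len(union)
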