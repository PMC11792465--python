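"""Core domain types and text-format readers/writers.

Every stage of the workflow exchanges data through the types defined here:
ASV count tables (:class:`FeatureTable`), compound peak-area tables
(:class:`CompoundTable`), per-feature LC-MS records (:class:`CompoundRecord`),
sample metadata with the HU/LCM treatment-unit rule (:class:`SampleMetadata`),
labelled distance matrices (:class:`DistanceMatrix`) and rooted phylogenies
(:class:`Tree`).

File conventions: UTF-8 TSV with a header row whose first cell is
``#SampleID`` for sample-indexed tables; newick for trees (branch lengths
mandatory everywhere except the root edge, which defaults to 0); a flat CSV
for vendor-style compound exports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("foodtrace")

SAMPLE_ID_HEADER = "#SampleID"

__all__ = [
    "FeatureTable",
    "CompoundTable",
    "CompoundRecord",
    "SampleMetadata",
    "DistanceMatrix",
    "Tree",
    "read_feature_table",
    "write_feature_table",
    "read_compound_table",
    "write_compound_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_compound_records",
    "write_compound_records",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class FeatureTable:
    """Samples x features table of non-negative integer counts."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray  # (n_samples, n_features), integer

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("counts shape does not match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=0):
                bad = np.argwhere(self.counts != rounded)[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"feature {self.feature_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    def relative_abundances(self) -> pd.DataFrame:
        """Sample-wise closure of counts to relative abundances."""
        totals = self.counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals[:, 0]) if t == 0]
            raise ValueError(f"samples with zero total counts: {empty}")
        return pd.DataFrame(
            self.counts / totals, index=self.sample_ids, columns=self.feature_ids
        )

    def presence(self) -> np.ndarray:
        return self.counts > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )


VALID_FRACTIONS = ("lipid", "aqueous")


@dataclass
class CompoundTable:
    """Samples x compounds table of non-negative peak areas.

    Each compound carries a ``fraction`` label (``lipid`` or ``aqueous``),
    the LC-MS extraction fraction it was measured in.
    """

    sample_ids: list[str]
    compound_ids: list[str]
    areas: np.ndarray  # (n_samples, n_compounds), float
    fractions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.compound_ids = [str(c) for c in self.compound_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.compound_ids, "compound")
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.compound_ids)):
            raise ValueError("areas shape does not match labels")
        if np.isnan(self.areas).any():
            logger.warning("missing compound areas read as 0")
            self.areas = np.nan_to_num(self.areas, nan=0.0)
        if (self.areas < 0).any():
            bad = np.argwhere(self.areas < 0)[0]
            raise ValueError(
                f"negative area at sample {self.sample_ids[bad[0]]!r}, "
                f"compound {self.compound_ids[bad[1]]!r}"
            )
        missing = [c for c in self.compound_ids if c not in self.fractions]
        if missing:
            raise ValueError(f"compounds without a fraction label: {missing[:5]}")
        for cid in self.compound_ids:
            if self.fractions[cid] not in VALID_FRACTIONS:
                raise ValueError(
                    f"unknown fraction {self.fractions[cid]!r} for compound {cid!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.areas.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.sample_ids, columns=self.compound_ids)

    def subset_compounds(self, compound_ids: Sequence[str]) -> "CompoundTable":
        idx = [self.compound_ids.index(c) for c in compound_ids]
        return CompoundTable(
            sample_ids=list(self.sample_ids),
            compound_ids=list(compound_ids),
            areas=self.areas[:, idx].copy(),
            fractions={c: self.fractions[c] for c in compound_ids},
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CompoundTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CompoundTable(
            sample_ids=list(sample_ids),
            compound_ids=list(self.compound_ids),
            areas=self.areas[idx, :].copy(),
            fractions=dict(self.fractions),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.compound_ids == other.compound_ids
            and np.allclose(self.areas, other.areas)
            and self.fractions == other.fractions
        )


@dataclass(frozen=True)
class CompoundRecord:
    """One LC-MS feature as exported by vendor software.

    ``area_m1`` is the monoisotopic (quantifier) peak area; ``area_m2`` the
    first C13 isotope peak, used as a qualifier when present; ``adduct_mass``
    an optional secondary charge-carrier mass used only as a qualifier.
    """

    compound_id: str
    neutral_mass: float  # Da
    rt: float  # minutes
    fraction: str
    area_m1: float
    annotation: str | None = None
    area_m2: float | None = None
    adduct_mass: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError(f"{self.compound_id}: neutral_mass must be > 0")
        if self.rt < 0:
            raise ValueError(f"{self.compound_id}: rt must be >= 0")
        if self.area_m1 < 0:
            raise ValueError(f"{self.compound_id}: area_m1 must be >= 0")
        if self.fraction not in VALID_FRACTIONS:
            raise ValueError(f"{self.compound_id}: unknown fraction {self.fraction!r}")


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's grouping metadata.

    ``treatment_unit`` is the pseudoreplication unit: the humanized-donor id
    for HU mice and the experimental cohort for LCM mice.
    """

    sample_id: str
    group: str  # "HU" or "LCM"
    donor_id: str | None
    cohort_id: str

    def __post_init__(self) -> None:
        if self.group not in ("HU", "LCM"):
            raise ValueError(f"{self.sample_id}: group must be HU or LCM, got {self.group!r}")
        if self.group == "HU" and not self.donor_id:
            raise ValueError(f"{self.sample_id}: HU sample requires donor_id")
        if not self.cohort_id:
            raise ValueError(f"{self.sample_id}: cohort_id required")

    @property
    def treatment_unit(self) -> str:
        return self.donor_id if self.group == "HU" else self.cohort_id


def treatment_units(metadata: Sequence[SampleMetadata]) -> dict[str, str]:
    """Mapping sample_id -> treatment unit."""
    return {m.sample_id: m.treatment_unit for m in metadata}


class DistanceMatrix:
    """Square, symmetric, hollow, non-negative matrix with sample labels."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        self.labels = [str(x) for x in labels]
        _check_unique(self.labels, "distance-matrix")
        v = np.asarray(values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix must be {n}x{n}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric within 1e-10")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-10).any():
            raise ValueError("distance matrix has negative entries")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


class Tree:
    """Rooted phylogeny with branch lengths, backed by a scikit-bio TreeNode.

    Branch lengths are mandatory on every edge except the root edge, which is
    treated as length 0 when absent.
    """

    def __init__(self, root: skbio.TreeNode):
        self.root = root
        if root.length is None:
            root.length = 0.0
        tips = list(root.tips())
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise ValueError("tree has unnamed tips")
        _check_unique(names, "tip")
        for node in root.traverse(include_self=False):
            if node.length is None:
                where = node.name or "internal node"
                raise ValueError(f"missing branch length at {where}")
            if not math.isfinite(node.length) or node.length < 0:
                raise ValueError(f"invalid branch length {node.length} at {node.name}")
        self.tip_names = names

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def total_branch_length(self) -> float:
        return float(sum(n.length for n in self.root.traverse(include_self=False)))

    def branch_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-branch lengths and tip membership.

        Returns ``(lengths, membership)`` where row *b* of the boolean
        ``membership`` matrix marks the tips descending from branch *b*.
        The root edge is excluded; every other edge, including tip edges,
        is one row.
        """
        tip_pos = {name: i for i, name in enumerate(self.tip_names)}
        lengths: list[float] = []
        members: list[np.ndarray] = []
        below: dict[int, np.ndarray] = {}
        for node in self.root.postorder(include_self=True):
            if node.is_tip():
                vec = np.zeros(self.n_tips, dtype=bool)
                vec[tip_pos[node.name]] = True
            else:
                vec = np.zeros(self.n_tips, dtype=bool)
                for child in node.children:
                    vec |= below[id(child)]
            below[id(node)] = vec
            if node is not self.root:
                lengths.append(float(node.length))
                members.append(vec)
        return np.asarray(lengths), np.asarray(members)

    def __str__(self) -> str:
        return str(self.root)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_indexed_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample label: {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = df.columns[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"duplicate feature label: {dup!r}")
    return df


def read_feature_table(path: str | Path, transposed: bool = False) -> FeatureTable:
    """Read a samples x features count TSV (features x samples with ``transposed``)."""
    df = _read_indexed_tsv(path)
    if transposed:
        df = df.T
    values = df.to_numpy()
    table = FeatureTable(list(df.index), list(df.columns), values)
    empty = [s for s, t in zip(table.sample_ids, table.counts.sum(axis=1)) if t == 0]
    if empty:
        raise ValueError(f"samples with no positive counts: {empty}")
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = SAMPLE_ID_HEADER
    df.to_csv(path, sep="\t")


def read_compound_table(path: str | Path, fractions_path: str | Path) -> CompoundTable:
    """Read areas TSV plus a two-column ``compound_id<TAB>fraction`` TSV."""
    df = _read_indexed_tsv(path)
    frac = pd.read_csv(fractions_path, sep="\t", dtype=str)
    fractions = dict(zip(frac.iloc[:, 0], frac.iloc[:, 1]))
    return CompoundTable(list(df.index), list(df.columns), df.to_numpy(dtype=float), fractions)


def write_compound_table(table: CompoundTable, path: str | Path, fractions_path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = SAMPLE_ID_HEADER
    df.to_csv(path, sep="\t")
    pd.DataFrame(
        {"compound_id": table.compound_ids,
         "fraction": [table.fractions[c] for c in table.compound_ids]}
    ).to_csv(fractions_path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = {c.lstrip("#").lower(): c for c in df.columns}
    required = ["sampleid", "group", "donor_id", "cohort_id"]
    for r in required:
        if r not in cols:
            raise ValueError(f"metadata missing column {r!r}")
    out = []
    for _, row in df.iterrows():
        donor = row[cols["donor_id"]] or None
        out.append(
            SampleMetadata(
                sample_id=row[cols["sampleid"]],
                group=row[cols["group"]],
                donor_id=donor,
                cohort_id=row[cols["cohort_id"]],
            )
        )
    _check_unique([m.sample_id for m in out], "sample")
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            SAMPLE_ID_HEADER: [m.sample_id for m in metadata],
            "group": [m.group for m in metadata],
            "donor_id": [m.donor_id or "" for m in metadata],
            "cohort_id": [m.cohort_id for m in metadata],
        }
    ).to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path) -> Tree:
    root = skbio.TreeNode.read(str(path), convert_underscores=False)
    return Tree(root)


def parse_tree(newick: str) -> Tree:
    import io as _io

    root = skbio.TreeNode.read(_io.StringIO(newick), convert_underscores=False)
    return Tree(root)


def write_tree(tree: Tree, path: str | Path) -> None:
    tree.root.write(str(path))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_indexed_tsv(path)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column labels differ")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = dm.to_dataframe()
    df.index.name = SAMPLE_ID_HEADER
    df.to_csv(path, sep="\t")


_RECORD_COLUMNS = [
    "compound_id", "annotation", "mass", "rt", "fraction",
    "sample_id", "area_m1", "area_m2", "adduct_mass",
]


def read_compound_records(path: str | Path) -> dict[str, list[CompoundRecord]]:
    """Read a vendor-style compound export CSV into per-sample record lists."""
    df = pd.read_csv(path)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"compound export missing columns {missing}")
    out: dict[str, list[CompoundRecord]] = {}
    for _, row in df.iterrows():
        rec = CompoundRecord(
            compound_id=str(row["compound_id"]),
            annotation=None if pd.isna(row["annotation"]) else str(row["annotation"]),
            neutral_mass=float(row["mass"]),
            rt=float(row["rt"]),
            fraction=str(row["fraction"]),
            sample_id=str(row["sample_id"]),
            area_m1=0.0 if pd.isna(row["area_m1"]) else float(row["area_m1"]),
            area_m2=None if pd.isna(row["area_m2"]) else float(row["area_m2"]),
            adduct_mass=None if pd.isna(row["adduct_mass"]) else float(row["adduct_mass"]),
        )
        out.setdefault(rec.sample_id, []).append(rec)
    return out


def write_compound_records(samples: Mapping[str, Iterable[CompoundRecord]], path: str | Path) -> None:
    rows = []
    for sample_id, records in samples.items():
        for r in records:
            rows.append(
                {
                    "compound_id": r.compound_id,
                    "annotation": r.annotation,
                    "mass": r.neutral_mass,
                    "rt": r.rt,
                    "fraction": r.fraction,
                    "sample_id": sample_id,
                    "area_m1": r.area_m1,
                    "area_m2": r.area_m2,
                    "adduct_mass": r.adduct_mass,
                }
            )
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)
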