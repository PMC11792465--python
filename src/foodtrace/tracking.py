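"""Targeted tracking of extract-derived compounds into plasma.

The workflow mirrors a targeted LC-MS data-extraction strategy: a compound
list is defined from replicate extract injections (a feature must appear in
100% of extract samples and in no preparatory blank), each listed compound is
then searched for in every plasma sample within a ppm mass window and a
retention-time window, matches are qualified by their isotope (M2/M1) ratio
and optional second charge carrier, low-evidence compounds are dropped by a
minimum-samples/minimum-area rule, and finally any compound also matched in
plasma from animals never given the extract (baseline samples) is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CompoundRecord, CompoundTable

__all__ = [
    "MatchParams",
    "TrackingReport",
    "mass_match",
    "define_extract_compounds",
    "match_to_plasma",
    "apply_detection_filters",
    "remove_baseline",
    "track",
]


@dataclass(frozen=True)
class MatchParams:
    """Windows and thresholds for targeted feature matching.

    Units: ppm for the mass window, minutes for retention-time windows,
    peak-area counts for the detection thresholds.
    """

    ppm_window: float = 10.0
    rt_window: float = 0.2
    rt_outlier: float = 0.3
    qualifier_rel_uncertainty: float = 0.20
    min_samples: int = 3
    min_area_aqueous: float = 20_000.0
    min_area_lipid: float = 55_000.0
    extract_rt_max: float = 10.0
    plasma_rt_max_lipid: float = 10.4
    plasma_rt_max_aqueous: float = 13.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"MatchParams.{name} must be positive")
        if self.ppm_window > 100:
            raise ValueError("ppm_window must be <= 100")

    def min_area(self, fraction: str) -> float:
        if fraction == "aqueous":
            return self.min_area_aqueous
        if fraction == "lipid":
            return self.min_area_lipid
        raise ValueError(f"unknown fraction label {fraction!r}")

    def plasma_rt_max(self, fraction: str) -> float:
        if fraction == "aqueous":
            return self.plasma_rt_max_aqueous
        if fraction == "lipid":
            return self.plasma_rt_max_lipid
        raise ValueError(f"unknown fraction label {fraction!r}")


@dataclass
class TrackingReport:
    """Compound accounting through the filtering cascade.

    The conservation identity ``n_retained = n_detected - n_baseline_removed``
    holds per fraction and in total; it is asserted at construction.
    """

    n_extract_compounds: int
    n_detected: dict[str, int]
    n_baseline_removed: dict[str, int]
    n_retained: dict[str, int] = field(default_factory=dict)
    retained: CompoundTable | None = None

    def __post_init__(self) -> None:
        if not self.n_retained:
            self.n_retained = {
                f: self.n_detected[f] - self.n_baseline_removed.get(f, 0)
                for f in self.n_detected
            }
        for f in self.n_detected:
            got = self.n_retained.get(f, 0)
            want = self.n_detected[f] - self.n_baseline_removed.get(f, 0)
            if got != want:
                raise ValueError(
                    f"accounting violated for fraction {f!r}: "
                    f"{got} retained != {self.n_detected[f]} detected - "
                    f"{self.n_baseline_removed.get(f, 0)} removed"
                )

    @classmethod
    def from_counts(
        cls, detected: Mapping[str, int], baseline_removed: Mapping[str, int]
    ) -> "TrackingReport":
        """Build a report from per-fraction detected/removed counts alone."""
        return cls(
            n_extract_compounds=sum(detected.values()),
            n_detected=dict(detected),
            n_baseline_removed=dict(baseline_removed),
        )

    @property
    def total_detected(self) -> int:
        return sum(self.n_detected.values())

    @property
    def total_baseline_removed(self) -> int:
        return sum(self.n_baseline_removed.values())

    @property
    def total_retained(self) -> int:
        return sum(self.n_retained.values())

    def to_dict(self) -> dict:
        return {
            "n_extract_compounds": self.n_extract_compounds,
            "n_detected": dict(self.n_detected),
            "n_baseline_removed": dict(self.n_baseline_removed),
            "n_retained": dict(self.n_retained),
            "total_detected": self.total_detected,
            "total_baseline_removed": self.total_baseline_removed,
            "total_retained": self.total_retained,
        }


def mass_match(query_mass: float, candidate_mass: float, ppm_window: float) -> bool:
    """True iff the candidate lies within ``ppm_window`` ppm of the query mass."""
    if query_mass <= 0 or candidate_mass <= 0:
        raise ValueError("masses must be positive")
    return abs(candidate_mass - query_mass) / query_mass * 1e6 <= ppm_window


def _rt_match(query_rt: float, candidate_rt: float, params: MatchParams) -> bool:
    drt = abs(candidate_rt - query_rt)
    return drt <= params.rt_window and drt <= params.rt_outlier


def _find_match(
    query: CompoundRecord, records: Sequence[CompoundRecord], params: MatchParams
) -> CompoundRecord | None:
    """Best same-fraction record within the mass and RT windows, or None.

    Ties break by smallest |delta ppm|, then smallest |delta rt|, then
    lexicographically lowest record compound_id, so output is deterministic.
    """
    best: tuple[float, float, str] | None = None
    best_rec: CompoundRecord | None = None
    for rec in records:
        if rec.fraction != query.fraction:
            continue
        if not mass_match(query.neutral_mass, rec.neutral_mass, params.ppm_window):
            continue
        if not _rt_match(query.rt, rec.rt, params):
            continue
        key = (
            abs(rec.neutral_mass - query.neutral_mass) / query.neutral_mass * 1e6,
            abs(rec.rt - query.rt),
            rec.compound_id,
        )
        if best is None or key < best:
            best, best_rec = key, rec
    return best_rec


def _qualifies(query: CompoundRecord, rec: CompoundRecord, params: MatchParams) -> bool:
    """Isotope-ratio and adduct qualification of a candidate match.

    The expected M2/M1 ratio comes from the extract record itself; a plasma
    record with no M2 peak is not disqualified (M1-only qualification).
    """
    if rec.area_m2 is not None and query.area_m2 is not None and query.area_m1 > 0:
        expected = query.area_m2 / query.area_m1
        if expected > 0 and rec.area_m1 > 0:
            observed = rec.area_m2 / rec.area_m1
            if abs(observed - expected) / expected > params.qualifier_rel_uncertainty:
                return False
    if rec.adduct_mass is not None and query.adduct_mass is not None:
        if not mass_match(query.adduct_mass, rec.adduct_mass, params.ppm_window):
            return False
    return True


def define_extract_compounds(
    extract_samples: Sequence[Sequence[CompoundRecord]],
    blank_samples: Sequence[Sequence[CompoundRecord]],
    params: MatchParams = MatchParams(),
) -> list[CompoundRecord]:
    """Consensus extract compound list.

    A compound (anchored on the first extract sample's records) is kept iff
    it is matched in every extract sample, elutes before ``extract_rt_max``,
    and is matched in no blank. The representative mass/RT/isotope areas are
    arithmetic means over the per-extract matches.
    """
    if len(extract_samples) == 0:
        raise ValueError("at least one extract sample is required")
    consensus: list[CompoundRecord] = []
    for anchor in extract_samples[0]:
        if anchor.rt >= params.extract_rt_max:
            continue
        matches = [anchor]
        for other in extract_samples[1:]:
            hit = _find_match(anchor, other, params)
            if hit is None:
                break
            matches.append(hit)
        else:
            rep = CompoundRecord(
                compound_id=anchor.compound_id,
                annotation=anchor.annotation,
                neutral_mass=float(np.mean([m.neutral_mass for m in matches])),
                rt=float(np.mean([m.rt for m in matches])),
                fraction=anchor.fraction,
                area_m1=float(np.mean([m.area_m1 for m in matches])),
                area_m2=(
                    float(np.mean([m.area_m2 for m in matches if m.area_m2 is not None]))
                    if any(m.area_m2 is not None for m in matches)
                    else None
                ),
                adduct_mass=anchor.adduct_mass,
            )
            if any(_find_match(rep, blank, params) for blank in blank_samples):
                continue
            consensus.append(rep)
    return consensus


def _apply_rt_ceiling(
    records: Sequence[CompoundRecord], params: MatchParams
) -> list[CompoundRecord]:
    return [r for r in records if r.rt < params.plasma_rt_max(r.fraction)]


def match_to_plasma(
    extract: Sequence[CompoundRecord],
    plasma: Mapping[str, Sequence[CompoundRecord]],
    params: MatchParams = MatchParams(),
) -> CompoundTable:
    """Targeted extraction of the consensus compound list from plasma samples.

    Records an M1 area per (extract compound, plasma sample); unmatched or
    disqualified cells get area 0. Plasma records past the per-fraction RT
    ceiling are discarded up front.
    """
    if len(extract) == 0:
        raise ValueError("extract compound list is empty")
    sample_ids = list(plasma.keys())
    filtered = {s: _apply_rt_ceiling(plasma[s], params) for s in sample_ids}
    areas = np.zeros((len(sample_ids), len(extract)))
    for j, query in enumerate(extract):
        for i, s in enumerate(sample_ids):
            hit = _find_match(query, filtered[s], params)
            if hit is not None and _qualifies(query, hit, params):
                areas[i, j] = hit.area_m1
    return CompoundTable(
        sample_ids=sample_ids,
        compound_ids=[c.compound_id for c in extract],
        areas=areas,
        fractions={c.compound_id: c.fraction for c in extract},
    )


def apply_detection_filters(
    matched: CompoundTable, params: MatchParams = MatchParams()
) -> CompoundTable:
    """Keep compounds detected in >= ``min_samples`` samples at the
    fraction-specific minimum area (inclusive); surviving compounds keep all
    their areas, including sub-threshold ones."""
    keep = []
    for j, cid in enumerate(matched.compound_ids):
        thresh = params.min_area(matched.fractions[cid])
        n_hits = int(np.count_nonzero(
            (matched.areas[:, j] >= thresh) & (matched.areas[:, j] > 0)
        ))
        if n_hits >= params.min_samples:
            keep.append(cid)
    return matched.subset_compounds(keep)


def remove_baseline(
    tracked: CompoundTable,
    baseline_plasma: Mapping[str, Sequence[CompoundRecord]],
    extract: Sequence[CompoundRecord],
    params: MatchParams = MatchParams(),
) -> TrackingReport:
    """Drop tracked compounds that also match in any baseline plasma sample.

    Baseline samples come from animals never exposed to the extract, so a
    match there marks the compound as endogenous/dietary background rather
    than extract-derived.
    """
    by_id = {c.compound_id: c for c in extract}
    baseline_filtered = [
        _apply_rt_ceiling(recs, params) for recs in baseline_plasma.values()
    ]
    removed: set[str] = set()
    for cid in tracked.compound_ids:
        query = by_id[cid]
        if any(_find_match(query, recs, params) is not None for recs in baseline_filtered):
            removed.add(cid)
    retained_ids = [c for c in tracked.compound_ids if c not in removed]
    retained = tracked.subset_compounds(retained_ids)
    fractions = sorted({tracked.fractions[c] for c in tracked.compound_ids})
    n_detected = {
        f: sum(1 for c in tracked.compound_ids if tracked.fractions[c] == f)
        for f in fractions
    }
    n_removed = {
        f: sum(1 for c in removed if tracked.fractions[c] == f) for f in fractions
    }
    return TrackingReport(
        n_extract_compounds=len(extract),
        n_detected=n_detected,
        n_baseline_removed=n_removed,
        retained=retained,
    )


def track(
    extract_samples: Sequence[Sequence[CompoundRecord]],
    blank_samples: Sequence[Sequence[CompoundRecord]],
    plasma: Mapping[str, Sequence[CompoundRecord]],
    baseline_plasma: Mapping[str, Sequence[CompoundRecord]],
    params: MatchParams = MatchParams(),
) -> TrackingReport:
    """Full cascade: define extract list, match into plasma, filter, subtract
    baseline. Returns the accounting report with the retained table."""
    extract = define_extract_compounds(extract_samples, blank_samples, params)
    matched = match_to_plasma(extract, plasma, params)
    detected = apply_detection_filters(matched, params)
    return remove_baseline(detected, baseline_plasma, extract, params)
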