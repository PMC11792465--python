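"""Shared result row type for compound-level screens."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


@dataclass
class ScreenResult:
    """One row of a compound-level (or compound x taxon) test."""

    feature_id: str
    statistic: float | None
    effect_size: float | None
    p_value: float | None
    p_adjusted: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    extra: dict = field(default_factory=dict)


def screen_table(rows: Sequence[ScreenResult]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {
            "feature_id": r.feature_id,
            "statistic": r.statistic,
            "effect_size": r.effect_size,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
        }
        rec.update(r.extra)
        records.append(rec)
    return pd.DataFrame(records)
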