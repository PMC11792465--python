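"""Compound vs Faith's PD regressions with cluster-robust errors.

Per compound: z-scored abundance regressed on phylogenetic diversity across
all 29 mice, CR1 standard errors clustered on the treatment unit, DFFITS > 1
exclusion, BH adjustment across survivors.
"""

import pandas as pd

from common import RESULTS, load_tracked, load_world
from foodtrace.diversity import DiversityVector
from foodtrace.regression import diversity_screen
from foodtrace.results import screen_table


def main() -> None:
    world = load_world()
    compounds = load_tracked()
    pd_series = pd.read_csv(RESULTS / "faith_pd.tsv", sep="\t", index_col=0)["faith_pd"]
    pd_vec = DiversityVector(list(pd_series.index), pd_series.to_numpy())

    rows = diversity_screen(compounds, pd_vec, world["metadata"])
    screen_table(rows).to_csv(RESULTS / "diversity_screen.tsv", sep="\t", index=False)
    ok = [r for r in rows if not r.excluded]
    sig = sorted(
        (r for r in ok if r.p_adjusted < 0.05), key=lambda r: r.p_adjusted
    )
    print(f"tested {len(ok)} compounds ({len(rows) - len(ok)} excluded by DFFITS)")
    print(f"adjusted p < 0.05: {len(sig)}")
    for r in sig[:8]:
        print(f"  {r.feature_id}: slope {r.effect_size:+.3f} SD/PD-unit, "
              f"adj p {r.p_adjusted:.2e}")


if __name__ == "__main__":
    main()
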