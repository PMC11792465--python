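"""Pairwise compound x taxon mixed-effects screens.

For every (compound, taxon) pair: z(compound) ~ arcsinh(100 * rel_abund) with
a random intercept per treatment unit (REML, Satterthwaite df), dropping
pairs with leave-one-out influence >= 4, BH across retained pairs. Run on
all mice and again restricted to humanized mice only.
"""

import numpy as np

from common import RESULTS, load_tracked, load_world
from foodtrace.io import FeatureTable
from foodtrace.regression import taxon_screen
from foodtrace.results import screen_table

N_TAXA = 15  # highest-variance taxa on the arcsinh-percent scale


def main() -> None:
    world = load_world()
    compounds = load_tracked()
    taxa = world["feature_table"]
    spread = np.arcsinh(100 * taxa.relative_abundances().to_numpy()).std(axis=0, ddof=1)
    top = np.argsort(-spread)[:N_TAXA]
    taxa_top = FeatureTable(
        list(taxa.sample_ids), [taxa.feature_ids[i] for i in top], taxa.counts[:, top]
    )
    for label, hu_only in (("all_mice", False), ("hu_only", True)):
        rows = taxon_screen(compounds, taxa_top, world["metadata"], hu_only=hu_only)
        screen_table(rows).to_csv(
            RESULTS / f"taxon_screen_{label}.tsv", sep="\t", index=False
        )
        ok = [r for r in rows if not r.excluded]
        sig = sorted((r for r in ok if r.p_adjusted < 0.05), key=lambda r: r.p_adjusted)
        print(f"{label}: {len(rows)} pairs, {len(rows) - len(ok)} excluded, "
              f"{len(sig)} significant after BH")
        for r in sig[:5]:
            print(f"  {r.extra['compound']} ~ {r.extra['taxon']}: "
                  f"beta {r.effect_size:+.3f}, adj p {r.p_adjusted:.2e}")


if __name__ == "__main__":
    main()
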