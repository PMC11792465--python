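"""Per-compound PERMANOVA of microbiome composition on compound abundance.

On treatment-unit centroids: one continuous-predictor PERMANOVA per tracked
compound against the UniFrac distance matrix (10^4 permutations), BH-adjusted
across compounds.
"""

from common import N_PERMUTATIONS, RESULTS, SEED, load_tracked, load_world
from foodtrace.community import (
    collapse_abundances,
    collapse_to_centroids,
    compound_composition_screen,
)
from foodtrace.io import read_distance_matrix, treatment_units
from foodtrace.results import screen_table


def main() -> None:
    world = load_world()
    compounds = load_tracked()
    unifrac = read_distance_matrix(RESULTS / "unifrac.tsv")
    units = treatment_units(world["metadata"])
    dm_c = collapse_to_centroids(unifrac, units)
    comp_c = collapse_abundances(compounds.subset_samples(unifrac.labels), units)

    rows = compound_composition_screen(dm_c, comp_c, n_perm=N_PERMUTATIONS, seed=SEED)
    screen_table(rows).to_csv(RESULTS / "composition_screen.tsv", sep="\t", index=False)
    ok = [r for r in rows if not r.excluded]
    raw = [r for r in ok if r.p_value < 0.05]
    adj = [r for r in ok if r.p_adjusted < 0.05]
    print(f"tested {len(ok)} compounds on {len(dm_c.labels)} centroids")
    print(f"raw p < 0.05:      {len(raw)} ({', '.join(r.feature_id for r in raw)})")
    print(f"adjusted p < 0.05: {len(adj)}")


if __name__ == "__main__":
    main()
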