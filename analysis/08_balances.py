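"""Log-ratio balance search for the compounds most associated with
microbiome composition.

Takes the 12 compounds with the smallest raw PERMANOVA p from the
composition screen and, on treatment-unit centroids, searches for the taxon
balance best explaining each compound's abundance (greedy selbal-style, with
cross-validated R^2).
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, SEED, load_tracked, load_world
from foodtrace.balances import select_balance
from foodtrace.community import collapse_abundances
from foodtrace.io import FeatureTable, read_distance_matrix, treatment_units

N_COMPOUNDS = 12


def main() -> None:
    world = load_world()
    compounds = load_tracked()
    unifrac = read_distance_matrix(RESULTS / "unifrac.tsv")
    units = treatment_units(world["metadata"])
    screen = pd.read_csv(RESULTS / "composition_screen.tsv", sep="\t")
    ranked = screen[~screen["excluded"]].sort_values(["p_value", "feature_id"])
    top_ids = ranked["feature_id"].head(N_COMPOUNDS).tolist()

    comp_c = collapse_abundances(compounds.subset_samples(unifrac.labels), units)
    taxa = world["feature_table"]
    order = [taxa.sample_ids.index(s) for s in unifrac.labels]
    unit_order = list(dict.fromkeys(units[s] for s in unifrac.labels))
    counts = np.vstack([
        taxa.counts[[order[i] for i, s in enumerate(unifrac.labels) if units[s] == u]].sum(axis=0)
        for u in unit_order
    ])
    taxa_c = FeatureTable(unit_order, list(taxa.feature_ids), counts)

    rng = np.random.default_rng(SEED)
    out = {}
    for cid in top_ids:
        j = comp_c.compound_ids.index(cid)
        bal = select_balance(
            taxa_c, comp_c.areas[:, j], seed=int(rng.integers(0, 2**31 - 1))
        )
        out[cid] = {
            "numerator": bal.numerator,
            "denominator": bal.denominator,
            "r_squared": bal.r_squared,
            "cv_r_squared": bal.cv_r_squared,
        }
        print(f"{cid}: {'+'.join(bal.numerator)} / {'+'.join(bal.denominator)}  "
              f"R^2 {bal.r_squared:.2f}, CV R^2 {bal.cv_r_squared:.2f}")

    with open(RESULTS / "balances.json", "w") as fh:
        json.dump(out, fh, indent=1)


if __name__ == "__main__":
    main()
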