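"""Centroid collapsing, PCoA and per-fraction Procrustes randomization.

Collapses the 29 mice to 13 treatment-unit centroids (donor for HU, cohort
for LCM) to avoid pseudoreplication, embeds the microbiome UniFrac centroids
and each compound fraction's Bray-Curtis centroids by PCoA, and tests their
concordance with the m^2 randomization test.
"""

import json

import numpy as np

from common import N_PERMUTATIONS, RESULTS, SEED, load_tracked, load_world
from foodtrace.community import collapse_abundances, collapse_to_centroids
from foodtrace.diversity import bray_curtis
from foodtrace.io import read_distance_matrix, treatment_units
from foodtrace.ordination import pcoa, procrustes_randomization_test


def main() -> None:
    world = load_world()
    compounds = load_tracked()
    unifrac = read_distance_matrix(RESULTS / "unifrac.tsv")
    units = treatment_units(world["metadata"])

    unifrac_centroids = collapse_to_centroids(unifrac, units)
    compound_centroids = collapse_abundances(
        compounds.subset_samples(unifrac.labels), units
    )
    micro_ord = pcoa(unifrac_centroids)
    print(f"collapsed {len(unifrac.labels)} mice -> {len(unifrac_centroids.labels)} units")

    rng = np.random.default_rng(SEED)
    out = {}
    for fraction in ("lipid", "aqueous"):
        ids = [
            c
            for c in compound_centroids.compound_ids
            if compound_centroids.fractions[c] == fraction
        ]
        bc = bray_curtis(compound_centroids.subset_compounds(ids))
        comp_ord = pcoa(bc.reorder(unifrac_centroids.labels))
        res = procrustes_randomization_test(
            micro_ord.coordinates,
            comp_ord.coordinates,
            n_perm=N_PERMUTATIONS,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out[fraction] = {"m2": res.m_squared, "p": res.p_value, "n_perm": N_PERMUTATIONS}
        print(f"{fraction:8s}: m^2 = {res.m_squared:.3f}, p = {res.p_value:.4f}")

    with open(RESULTS / "procrustes.json", "w") as fh:
        json.dump(out, fh, indent=1)


if __name__ == "__main__":
    main()
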