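"""Generate the synthetic study and write every pipeline input.

Emulates the design: 10 humanized donor microbiomes x 2 replicate mice plus
9 low-complexity mice in 3 cohorts, a compound table with planted taxon-,
diversity- and balance-linked effects, and vendor-style LC-MS feature lists
(4 extract replicates, blanks, per-mouse plasma, baseline plasma).
"""

import json

from common import SEED, WORLD, ensure_world, load_world


def main() -> None:
    ensure_world()
    world = load_world()
    truth = world["ground_truth"]
    table = world["feature_table"]
    print(f"world written under {WORLD} (seed {SEED})")
    print(f"  microbiome: {table.shape[0]} samples x {table.shape[1]} ASVs")
    print(f"  planted taxon-linked compounds:    {len(truth['taxon_pairs'])}")
    print(f"  planted diversity-linked:          {len(truth['diversity_compounds'])}")
    print(f"  planted balance-linked:            {len(truth['balance_compounds'])}")
    print(f"  baseline (to be removed):          {len(truth['baseline_compounds'])}")
    print(f"  decoy LC-MS features:              {len(truth['decoy_ids'])}")
    print(json.dumps({"seed": SEED}, indent=1))


if __name__ == "__main__":
    main()
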