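"""Shared paths and world loading for the numbered analysis drivers.

The drivers operate on a synthetic study written under ``results/world``;
run ``01_simulate_world.py`` first (any driver will generate the world
automatically if it is missing, using the same fixed seed).
"""

from __future__ import annotations

import json
from pathlib import Path

from foodtrace import io as ftio
from foodtrace.simulate import SimConfig, generate_world

SEED = 7
N_PERMUTATIONS = 9_999
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
WORLD = RESULTS / "world"


def ensure_world() -> None:
    """Write the synthetic study's input files if they are not on disk."""
    if (WORLD / "metadata.tsv").exists():
        return
    WORLD.mkdir(parents=True, exist_ok=True)
    world = generate_world(SimConfig(seed=SEED))
    ftio.write_feature_table(world["feature_table"], WORLD / "asv_counts.tsv")
    ftio.write_tree(world["tree"], WORLD / "tree.nwk")
    ftio.write_metadata(world["metadata"], WORLD / "metadata.tsv")
    for name in ("extract", "blanks", "plasma", "baseline"):
        ftio.write_compound_records(world["lcms"][name], WORLD / f"{name}.csv")
    with open(WORLD / "ground_truth.json", "w") as fh:
        json.dump(world["ground_truth"].to_dict(), fh, indent=1)


def load_world() -> dict:
    ensure_world()
    return {
        "feature_table": ftio.read_feature_table(WORLD / "asv_counts.tsv"),
        "tree": ftio.read_tree(WORLD / "tree.nwk"),
        "metadata": ftio.read_metadata(WORLD / "metadata.tsv"),
        "lcms": {
            name: ftio.read_compound_records(WORLD / f"{name}.csv")
            for name in ("extract", "blanks", "plasma", "baseline")
        },
        "ground_truth": json.load(open(WORLD / "ground_truth.json")),
    }


def load_tracked():
    path = RESULTS / "tracked_compounds.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_track_compounds.py first")
    return ftio.read_compound_table(path, RESULTS / "tracked_fractions.tsv")
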