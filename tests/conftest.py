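import numpy as np
import pytest

from foodtrace.io import FeatureTable, parse_tree
from foodtrace.simulate import SimConfig, generate_world


@pytest.fixture
def quartet_tree():
    """Balanced 4-tip tree with unit branch lengths (total length 6)."""
    return parse_tree("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def quartet_table():
    return FeatureTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C", "D"],
        np.array([[1, 1, 0, 0], [1, 0, 0, 0], [2, 1, 3, 4]]),
    )


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study shared by the integration-level tests."""
    cfg = SimConfig(
        n_asv=40,
        n_compounds=16,
        n_taxon_linked=2,
        n_diversity_linked=2,
        n_balance_linked=1,
        n_baseline=3,
        n_decoys=6,
        n_blank_contaminants=3,
        seed=11,
    )
    return cfg, generate_world(cfg)
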