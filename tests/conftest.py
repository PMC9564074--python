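import logging

import numpy as np
import pandas as pd
import pytest

from gutnet import CountTable, SyntheticConfig

# the degenerate-feature warnings are expected noise in simulation-heavy tests
logging.getLogger("gutnet").setLevel(logging.ERROR)


@pytest.fixture
def tiny_table() -> CountTable:
    """6 taxa x 4 samples, 2 groups, hand-checkable."""
    counts = pd.DataFrame(
        [
            [10, 5, 3, 1, 1, 0],
            [8, 6, 2, 2, 1, 1],
            [2, 1, 9, 6, 1, 1],
            [1, 2, 8, 7, 2, 0],
        ],
        index=["a1", "a2", "b1", "b2"],
        columns=[f"t{i}" for i in range(6)],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.index)
    return CountTable(counts, groups)


def make_config(**kwargs) -> SyntheticConfig:
    """Small two-group null configuration unless overridden."""
    base = dict(
        n_groups=2,
        n_samples_per_group=8,
        n_taxa=20,
        sequencing_depth=5_000,
        baseline_log_sd=1.0,
        n_pathways=5,
        seed=0,
    )
    base.update(kwargs)
    return SyntheticConfig(**base)


@pytest.fixture
def null_config() -> SyntheticConfig:
    return make_config()


def block_labels(block_spec_group) -> np.ndarray:
    """Planted block label per taxon for one group's block spec (-1 = none)."""
    labels = []
    for b, (size, _) in enumerate(block_spec_group):
        labels += [b] * size
    return np.asarray(labels)
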