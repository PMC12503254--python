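import numpy as np
import pytest

from sleepcca import (
    BlockMatrix,
    ConfoundTable,
    SyntheticConfig,
    generate_cohort,
    generate_phenotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blocks(rng, n=60, p=4, q=5):
    """Two independent random blocks for oracle comparisons."""
    X = BlockMatrix(rng.standard_normal((n, p)), [f"x{i}" for i in range(p)])
    Y = BlockMatrix(rng.standard_normal((n, q)), [f"y{i}" for i in range(q)])
    return X, Y


@pytest.fixture
def small_dataset():
    """A small planted dataset with family structure, ready for inference."""
    cfg = SyntheticConfig(n_subjects=200, n_bps_vars=16, seed=42)
    cohort = generate_cohort(cfg)
    X, Y, truth = generate_phenotypes(cfg, cohort)
    confounds = ConfoundTable.from_cohort(cohort)
    return cfg, cohort, X, Y, truth, confounds
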