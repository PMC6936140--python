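import numpy as np
import pandas as pd
import pytest

from stagenet.expression import ExpressionMatrix
from stagenet.synthetic import SyntheticConfig


def make_matrix(values, feature_ids=None, sample_ids=None, stage=None):
    """Build an ExpressionMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    stage = stage if stage is not None else {s: "I" for s in sample_ids}
    return ExpressionMatrix(pd.DataFrame(arr, index=feature_ids, columns=sample_ids), stage)


@pytest.fixture
def small_config():
    """A fast synthetic configuration for unit tests."""
    return SyntheticConfig(
        n_samples_per_stage=20,
        n_mirnas=10,
        n_genes=40,
        n_planted_pairs=8,
        n_communities=4,
        n_go_terms=12,
        seed=0,
    )
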