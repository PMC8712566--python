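import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_oracles importable


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_feature_table():
    """40-subject table with moderate class separation in a few features."""
    from eegfuse.synthetic import gen_feature_table

    return gen_feature_table(
        20,
        {"theta_leaf_fraction": 2.0, "beta_diameter": -1.5, "gamma_max_bc": 1.2},
        seed=711,
    )


@pytest.fixture(scope="session")
def fast_roster():
    return ("decision_tree", "knn", "svm_linear", "logistic_regression")
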