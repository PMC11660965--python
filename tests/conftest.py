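import numpy as np
import pytest

from mircascade.cascade_forest import CascadeConfig
from mircascade.data_io import AssociationMatrix, SimilarityMatrix
from mircascade.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def toy_adjacency():
    """3 miRNAs x 2 diseases with profiles (1,0), (0,1), (0,0)."""
    return AssociationMatrix(
        np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
        ["m1", "m2", "m3"],
        ["d1", "d2"],
    )


@pytest.fixture
def toy_mfs():
    values = np.array(
        [
            [1.0, 0.6, 0.0],
            [0.6, 1.0, 0.3],
            [0.0, 0.3, 1.0],
        ]
    )
    return SimilarityMatrix(values, ["m1", "m2", "m3"], "MFS")


@pytest.fixture
def toy_dss():
    values = np.array([[1.0, 0.4], [0.4, 1.0]])
    return SimilarityMatrix(values, ["d1", "d2"], "DSS")


@pytest.fixture(scope="session")
def synthetic_default():
    """Default planted-block dataset (seed 1), shared across tests."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture
def fast_cascade_config():
    """Small cascade for structural tests: few trees, 2 folds, 2 levels."""
    return CascadeConfig(
        n_trees_per_estimator=5, inner_folds=2, max_levels=2, seed=7
    )


@pytest.fixture
def blobs_xy():
    """Perfectly separable 2-D blobs, n=200, fixed seed."""
    rng = np.random.default_rng(0)
    n = 100
    x0 = rng.normal(loc=(-3.0, -3.0), scale=0.3, size=(n, 2))
    x1 = rng.normal(loc=(3.0, 3.0), scale=0.3, size=(n, 2))
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y
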