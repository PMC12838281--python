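import numpy as np
import pytest

from blendeeg import FeatureMatrix, make_feature_benchmark


def benchmark_matrix(
    n_samples=200, n_features=20, n_informative=5, class_sep=2.0, seed=0
) -> tuple[FeatureMatrix, np.ndarray]:
    """Planted benchmark wrapped as a FeatureMatrix, plus informative idx."""
    bm = make_feature_benchmark(n_samples, n_features, n_informative, class_sep, seed)
    F = FeatureMatrix(
        X=bm.X,
        y=bm.y,
        feature_names=[f"f{i}" for i in range(n_features)],
        subject_ids=np.array([f"s{i}" for i in range(n_samples)], dtype=object),
    )
    return F, bm.informative_idx


@pytest.fixture
def planted():
    return benchmark_matrix()


@pytest.fixture
def small_planted():
    return benchmark_matrix(n_samples=120, n_features=8, n_informative=3, seed=3)
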