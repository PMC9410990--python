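import numpy as np
import pytest

from lcnc import BinarySpec, FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs, n=20 each, p=2."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 0.0], 0.5, size=(20, 2))
    b = rng.normal([5.0, 5.0], 0.5, size=(20, 2))
    X = np.vstack([a, b])
    y = np.concatenate([np.ones(20), -np.ones(20)])
    return X, y


@pytest.fixture
def three_blob_table():
    """Separable 3-class table for OVR fixtures."""
    rng = np.random.default_rng(11)
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    rows, labels = [], []
    for c, mu in enumerate(centers, start=1):
        rows.append(rng.normal(mu, 0.4, size=(10, 2)))
        labels += [c] * 10
    X = np.vstack(rows)
    ids = [f"s{i}" for i in range(len(X))]
    return FeatureTable(X, ids, ["f1", "f2"], np.array(labels))


def fast_spec(classifier="plsda", seed=0, **kw):
    """Selection settings scaled down for test-sized problems."""
    defaults = dict(max_lv=4, n_splits=12, folds=4,
                    sigma_grid=None, gamma_grid=(0.1, 1.0, 10.0, 100.0))
    defaults.update(kw)
    return BinarySpec(classifier=classifier, seed=seed, **defaults)


@pytest.fixture
def fast_plsda_spec():
    return fast_spec("plsda")


@pytest.fixture
def fast_lssvm_spec():
    return fast_spec("lssvm")
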