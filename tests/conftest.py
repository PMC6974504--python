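import numpy as np
import pytest

from latentlens import (
    NeuralNet,
    PLSDA,
    SynthSpec,
    fit_transform_train,
    generate,
)


@pytest.fixture(scope="session")
def synth_table():
    """Default synthetic study: 50/50 samples, 52 metabolites, 5 informative
    at 2 SD, rank-2 shared covariance."""
    return generate(SynthSpec(seed=11))


@pytest.fixture(scope="session")
def scaled_data(synth_table):
    pt, truth = synth_table
    X, params = fit_transform_train(pt.X)
    return X, pt.class_labels.astype(float), truth


@pytest.fixture(scope="session")
def pls_fit(scaled_data):
    X, y, _ = scaled_data
    return PLSDA(X, y, n_components=2).fit()


@pytest.fixture(scope="session")
def ann_fit(scaled_data):
    X, y, _ = scaled_data
    return NeuralNet(X, y, n_hidden=2, learning_rate=0.03, seed=7).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
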