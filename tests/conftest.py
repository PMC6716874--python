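import numpy as np
import pytest

from contextflux.synthetic_data import (ExpressionSimSpec, ToyNetworkSpec,
                                        make_toy_network, simulate_expression)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_network(ToyNetworkSpec(seed=0))


@pytest.fixture(scope="session")
def toy_model_no_branch():
    return make_toy_network(ToyNetworkSpec(include_trp_branch=False, seed=0))


@pytest.fixture(scope="session")
def null_expression():
    """No batch effect, no DE: pure per-gene noise around baselines."""
    spec = ExpressionSimSpec(n_genes=2000, n_batches=2,
                             samples_per_condition_per_batch=10,
                             batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0),
                             noise_sd=0.5, seed=11)
    return simulate_expression([], spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
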