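import numpy as np
import pytest

from vnsnet import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_network():
    spec = synthetic.default_network_spec()
    prec_a, prec_b = synthetic.make_group_precisions(spec)
    return spec, prec_a, prec_b


@pytest.fixture(scope="session")
def planted_features():
    """Per-epoch partial-correlation features for 100 epochs/group drawn
    from the default planted two-group networks (unpenalized estimates for
    speed; shared across tests that only need group-separable features)."""
    from vnsnet import connectivity

    spec = synthetic.default_network_spec()
    prec_a, prec_b = synthetic.make_group_precisions(spec)
    rows, labels = [], []
    for g, (prec, lab) in enumerate([(prec_a, "responder"), (prec_b, "nonresponder")]):
        for k in range(100):
            epoch = synthetic.simulate_epoch_series(prec, 60, seed=50_000 * g + k)
            rows.append(connectivity.epoch_features(epoch, lam=0.0))
            labels.append(lab)
    return np.vstack(rows), np.array(labels), spec
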