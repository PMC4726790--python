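import pytest

import relbelief as rb


@pytest.fixture(scope="session")
def coin_model():
    """The packaged 20-flip dataset with its beta(4,4) prior."""
    return rb.BetaBernoulli.from_data(rb.coin_flips(), alpha0=4, beta0=4)


@pytest.fixture(scope="session")
def coin_fit():
    """Full fitted analysis of the packaged dataset at psi0 = 1/2."""
    model = rb.BernoulliEvidence(rb.coin_flips(), alpha0=4, beta0=4)
    return model.fit(psi0=0.5, gamma=0.95)
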