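import numpy as np
import pytest

from csnets.topology import (
    NeuronParams,
    derive_dendritic_params,
    make_dendritic_network,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dendritic_params():
    return NeuronParams.dendritic(
        lambda_V=10.0, lambda_s=10.0, lambda_x=2.0, mu=0.0, dt=5e-4
    )


@pytest.fixture
def small_dendritic_net(dendritic_params, rng):
    """A small, echo-state-satisfying dendritic CSN for fast tests."""
    spec = make_dendritic_network(
        60, 4, dendritic_params, rng, g=1.0, p=1.0, gamma_s=0.1
    )
    sv = np.linalg.svd(spec.A, compute_uv=False)[0]
    spec.A *= 1.5 / sv
    spec.D, spec.W, spec.U_tilde, spec.U, spec.theta_vec = derive_dendritic_params(
        spec.Gamma, spec.A, dendritic_params
    )
    return spec
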