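import numpy as np
import pytest

from csnets.topology import (
    NeuronParams,
    build_decoding_matrix,
    build_sparse_coupling,
    derive_dendritic_params,
    draw_io_weights,
)


class TestSparseCoupling:
    def test_zero_gain_gives_zero_matrix(self, rng):
        A = build_sparse_coupling(50, 0.1, 0.0, rng)
        assert np.all(A == 0.0)

    @pytest.mark.parametrize("dim,tol", [(200, 0.15), (1000, 0.10)])
    def test_spectral_radius_approaches_g(self, dim, tol):
        g = 1.5
        radii = []
        for seed in range(10):
            A = build_sparse_coupling(dim, 0.1, g, np.random.default_rng(seed))
            radii.append(np.abs(np.linalg.eigvals(A)).max())
        assert abs(np.mean(radii) - g) / g < tol

    def test_no_autapses_zeroes_diagonal(self, rng):
        A = build_sparse_coupling(200, 0.5, 1.0, rng, allow_autapses=False)
        assert np.all(np.diag(A) == 0.0)

    def test_sparsity_fraction(self, rng):
        A = build_sparse_coupling(300, 0.1, 1.0, rng)
        frac = np.count_nonzero(A) / A.size
        assert abs(frac - 0.1) < 0.01

    def test_degenerate_and_invalid_inputs(self, rng):
        with pytest.warns(UserWarning):
            build_sparse_coupling(2, 0.1, 1.0, rng)
        with pytest.raises(ValueError):
            build_sparse_coupling(10, 0.0, 1.0, rng)
        with pytest.raises(ValueError):
            build_sparse_coupling(10, 0.1, np.inf, rng)


class TestDecodingMatrix:
    def test_single_entry_is_signed_gamma_s(self, rng):
        G = build_decoding_matrix(1, 1, 0.5, rng)
        assert abs(abs(G[0, 0]) - 0.5) < 1e-14

    def test_all_column_norms_equal_gamma_s(self, rng):
        G = build_decoding_matrix(50, 500, 0.03, rng)
        norms = np.linalg.norm(G, axis=0)
        assert np.all(np.abs(norms - 0.03) < 1e-12)
        assert norms.max() - norms.min() < 1e-12

    def test_invalid_scale_raises(self, rng):
        with pytest.raises(ValueError):
            build_decoding_matrix(5, 10, 0.0, rng)


class TestDendriticCouplings:
    def test_identity_decoder_reduces_to_direct_coupling(self, rng):
        J = 6
        params = NeuronParams.dendritic(10.0, 10.0, 2.0, mu=0.0)
        A = rng.standard_normal((J, J))
        D, W, U_tilde, U, theta = derive_dendritic_params(np.eye(J), A, params)
        assert np.allclose(D, A)
        assert np.allclose(U, np.eye(J))
        assert np.allclose(theta, 0.5)
        assert np.allclose(U_tilde, params.a * np.eye(J))

    def test_mu_adds_exact_diagonal(self, rng):
        params = NeuronParams.dendritic(10.0, 10.0, 2.0, mu=0.1)
        G = rng.standard_normal((3, 10))
        _, _, _, U, _ = derive_dendritic_params(G, rng.standard_normal((3, 3)), params)
        assert np.allclose(U - G.T @ G, 0.1 * np.eye(10))

    @pytest.mark.parametrize("seed", range(6))
    def test_optimal_coupling_equalities(self, seed):
        """All derived-coupling interrelations hold to machine precision."""
        r = np.random.default_rng(seed)
        J, N = int(r.integers(1, 8)), int(r.integers(1, 30))
        mu = float(r.uniform(0, 0.2))
        params = NeuronParams.dendritic(10.0, 10.0, 2.0, mu=mu)
        G = r.standard_normal((J, N))
        A = r.standard_normal((J, J))
        D, W, U_tilde, U, theta = derive_dendritic_params(G, A, params)
        assert np.allclose(D, G.T @ A, atol=1e-14)
        assert np.allclose(W, G, atol=0)
        assert np.allclose(U_tilde, params.a * G.T @ G + mu * params.lambda_s * np.eye(N))
        assert np.allclose(U, G.T @ G + mu * np.eye(N))
        assert np.allclose(theta, np.diag(U) / 2.0)
        # symmetry and positive semidefiniteness of the quadratic couplings
        assert np.allclose(U, U.T)
        assert np.linalg.eigvalsh(U).min() > -1e-10

    def test_equal_column_norms_give_equal_thresholds(self, rng):
        params = NeuronParams.dendritic(10.0, 10.0, 2.0)
        G = build_decoding_matrix(5, 40, 0.2, rng)
        *_, theta = derive_dendritic_params(G, np.zeros((5, 5)), params)
        assert theta.max() - theta.min() < 1e-12

    def test_shape_mismatch_raises(self, rng):
        params = NeuronParams.dendritic(10.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            derive_dendritic_params(np.zeros((3, 5)), np.zeros((4, 4)), params)


class TestIOWeights:
    def test_zero_amplitude(self, rng):
        assert np.all(draw_io_weights(5, 4, 0.0, rng) == 0.0)

    def test_uniform_moments_and_support(self, rng):
        w = draw_io_weights(1000, 100, 1.0, rng)
        assert abs(w.mean()) < 0.02
        assert np.abs(w).max() <= 1.0

    def test_negative_amplitude_raises(self, rng):
        with pytest.raises(ValueError):
            draw_io_weights(2, 2, -1.0, rng)


class TestNeuronParams:
    def test_saturating_ties_lambda_x_to_recovery(self):
        p = NeuronParams.saturating(10.0, 10.0, theta=0.03, V_r=0.9 * 0.03)
        assert np.isclose(p.lambda_x, 1.0)
        assert np.isclose(p.a, p.lambda_s - p.lambda_x)
        assert p.gamma == p.theta  # default saturation scale

    def test_invariant_violations_raise(self):
        with pytest.raises(ValueError):
            NeuronParams(lambda_V=10.0, lambda_s=10.0, lambda_x=11.0, theta=0.03)
        with pytest.raises(ValueError):
            NeuronParams(lambda_V=10.0, lambda_s=10.0, lambda_x=1.0, theta=-1.0)
        with pytest.raises(ValueError):
            NeuronParams(lambda_V=10.0, lambda_s=10.0, lambda_x=1.0, theta=0.03, mu=-0.1)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestCouplingInterrelationsProperty:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        J=st.integers(1, 6),
        N=st.integers(1, 25),
        mu=st.floats(0.0, 0.5),
        seed=st.integers(0, 2**16),
    )
    def test_derived_couplings_satisfy_interrelations(self, J, N, mu, seed):
        """The optimal dendritic coupling set keeps its defining algebraic
        identities for arbitrary decoder/coupling draws."""
        r = np.random.default_rng(seed)
        params = NeuronParams.dendritic(10.0, 10.0, 2.0, mu=mu)
        G = r.standard_normal((J, N))
        A = r.standard_normal((J, J))
        D, W, U_tilde, U, theta = derive_dendritic_params(G, A, params)
        assert np.allclose(D, G.T @ A, atol=1e-12)
        assert np.allclose(U - G.T @ G, mu * np.eye(N), atol=1e-12)
        assert np.allclose(
            U_tilde - params.a * (G.T @ G), mu * params.lambda_s * np.eye(N), atol=1e-10
        )
        assert np.allclose(theta, np.diag(U) / 2.0)
        assert np.linalg.eigvalsh(U).min() > -1e-9
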