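import numpy as np
import pytest
from scipy.optimize import brentq

from csnets.simulate import (
    NetworkState,
    RunawayExcitationError,
    decode_dendritic,
    decode_saturating,
    process_spikes_dendritic,
    run_network,
    step_dendritic,
    step_saturating,
)
from csnets.topology import NetworkSpec, NeuronParams, make_saturating_network


def _single_saturating(theta=0.03, V_r=0.0, dt=1e-4):
    params = NeuronParams.saturating(10.0, 10.0, theta=theta, V_r=V_r, dt=dt)
    spec = NetworkSpec(variant="saturating", N=1, J=1, A=np.zeros((1, 1)))
    return spec, params


class TestSaturatingStep:
    def test_pure_leak_matches_exponential(self):
        spec, params = _single_saturating()
        state = NetworkState(t=0.0, V=np.array([0.01]), r=np.zeros(1))
        for _ in range(2000):
            step_saturating(state, spec, None, params)
        assert state.n_spikes() == 0
        expected = 0.01 * np.exp(-params.lambda_V * state.t)
        assert np.isclose(state.V[0], expected, rtol=1e-8)

    def test_constant_drive_rate_matches_event_driven_oracle(self):
        """Steady firing under constant input vs exact threshold crossings.

        Between spikes the scalar dynamics are linear, so the membrane
        trajectory has a closed form; root-finding its threshold crossing
        gives an event-driven reference simulation.
        """
        theta, V_r, I = 0.03, 0.9 * 0.03, 0.5
        spec, params = _single_saturating(theta=theta, V_r=V_r, dt=1e-4)
        lV, ls = params.lambda_V, params.lambda_s

        def V_closed(t, V0, r0):
            hom = V0 * np.exp(-lV * t)
            rec = V_r * ls * r0 * (np.exp(-ls * t) - np.exp(-lV * t)) / (lV - ls) \
                if abs(lV - ls) > 1e-12 else V_r * ls * r0 * t * np.exp(-lV * t)
            ext = (I / lV) * (1 - np.exp(-lV * t))
            return hom + rec + ext

        # event-driven reference: iterate exact crossings for 2 s
        t, V0, r0, n_spikes_ref = 0.0, 0.0, 0.0, 0
        while t < 2.0:
            f = lambda s: V_closed(s, V0, r0) - theta / 2
            hi = 1e-3
            while f(hi) < 0 and hi < 10.0:
                hi *= 1.5
            s = brentq(f, 1e-9, hi)
            V0 = theta / 2 - theta
            r0 = r0 * np.exp(-ls * s) + 1.0
            t += s
            if t < 2.0:
                n_spikes_ref += 1
        rate_ref = n_spikes_ref / 2.0

        state = NetworkState.zeros(1)
        for _ in range(int(2.0 / params.dt)):
            step_saturating(state, spec, np.array([I]), params)
        rate_grid = state.n_spikes() / 2.0
        assert abs(rate_grid - rate_ref) / rate_ref < 0.02

    def test_encoded_signal_continuous_across_spikes(self, rng):
        """x = V + theta*r is unchanged by the spike/reset action."""
        params = NeuronParams.saturating(10.0, 10.0, theta=0.03, V_r=0.9 * 0.03, dt=1e-3)
        spec = make_saturating_network(30, params, rng, g=1.5)
        state = NetworkState.random(spec, params, rng)
        drive = rng.uniform(0.2, 0.8, 30)
        saw_spike = False
        for _ in range(500):
            from csnets.simulate import _advance_smooth, _sat_dV

            _advance_smooth(state, spec, params, drive, None, "rk4", _sat_dV)
            x_before = decode_saturating(state.V, state.r, params.theta)
            spiking = state.V > params.theta / 2
            state.V[spiking] -= params.theta
            state.r[spiking] += 1.0
            x_after = decode_saturating(state.V, state.r, params.theta)
            if spiking.any():
                saw_spike = True
                assert np.abs(x_after - x_before).max() < 1e-9 * params.theta
        assert saw_spike

    def test_at_most_one_spike_per_neuron_per_step(self, rng):
        params = NeuronParams.saturating(10.0, 10.0, theta=0.01, V_r=0.0, dt=1e-3)
        spec = make_saturating_network(20, params, rng)
        state = NetworkState.zeros(20)
        for _ in range(200):
            before = state.r.copy()
            step_saturating(state, spec, np.full(20, 2.0), params)
            assert np.all(state.r - before * np.exp(0) <= before + 1.0 + 1e-9)
            if state.spike_ids:
                assert len(np.unique(state.spike_ids[-1])) == len(state.spike_ids[-1])

    def test_nonfinite_state_raises_with_neuron_index(self):
        spec, params = _single_saturating()
        state = NetworkState(t=0.0, V=np.array([np.nan]), r=np.zeros(1))
        with pytest.raises(FloatingPointError, match="neuron 0"):
            step_saturating(state, spec, None, params)


class TestDendriticStep:
    def test_zero_couplings_pure_leak(self, dendritic_params):
        J, N = 2, 5
        spec = NetworkSpec(
            variant="dendritic", N=N, J=J,
            A=np.zeros((J, J)), Gamma=np.zeros((J, N)), D=np.zeros((N, J)),
            W=np.zeros((J, N)), U_tilde=np.zeros((N, N)), U=np.zeros((N, N)),
            theta_vec=np.full(N, 0.5),
        )
        v0 = 0.3
        state = NetworkState(t=0.0, V=np.full(N, v0), r=np.zeros(N))
        for _ in range(1000):
            step_dendritic(state, spec, None, dendritic_params)
        assert np.allclose(
            state.V, v0 * np.exp(-dendritic_params.lambda_V * state.t), rtol=1e-8
        )

    def test_subthreshold_state_unchanged_by_spike_processing(self, small_dendritic_net):
        state = NetworkState.zeros(small_dendritic_net.N)
        state.V[:] = 0.5 * small_dendritic_net.theta_vec
        V0 = state.V.copy()
        _, spikes = process_spikes_dendritic(state, small_dendritic_net)
        assert len(spikes) == 0
        assert np.array_equal(state.V, V0)

    def test_mutual_inhibition_allows_single_spike(self):
        """Two neurons with identical decoding columns: the first spike's
        fast inhibition pushes the second below threshold."""
        G = np.array([[0.5, 0.5]])  # identical columns
        params = NeuronParams.dendritic(10.0, 10.0, 2.0)
        from csnets.topology import derive_dendritic_params

        D, W, U_tilde, U, theta = derive_dendritic_params(G, np.zeros((1, 1)), params)
        spec = NetworkSpec(
            variant="dendritic", N=2, J=1, A=np.zeros((1, 1)), Gamma=G,
            D=D, W=W, U_tilde=U_tilde, U=U, theta_vec=theta,
        )
        state = NetworkState(t=0.0, V=np.array([0.15, 0.14]), r=np.zeros(2))
        _, spikes = process_spikes_dendritic(state, spec)
        assert list(spikes) == [0]
        assert state.r[0] == 1.0 and state.r[1] == 0.0
        # hand-computed fast interaction: V -= U[:, 0] with U = G^T G
        assert np.allclose(state.V, [0.15 - 0.25, 0.14 - 0.25])

    def test_always_minus_theta_reset_is_absolute(self, small_dendritic_net):
        spec = small_dendritic_net
        spec.reset_mode = "always_minus_theta"
        state = NetworkState.zeros(spec.N)
        # only neuron n can spike; everyone else is far below threshold
        state.V[:] = -100.0 * spec.theta_vec
        n = 3
        state.V[n] = 5.0 * spec.theta_vec[n]  # strongly suprathreshold
        _, spikes = process_spikes_dendritic(state, spec)
        assert list(spikes) == [n]
        assert np.isclose(state.V[n], -spec.theta_vec[n])

    def test_runaway_excitation_raises(self):
        # pathological self-exciting fast coupling: spiking raises V again
        params = NeuronParams.dendritic(10.0, 10.0, 2.0)
        N = 4
        spec = NetworkSpec(
            variant="dendritic", N=N, J=N, A=np.zeros((N, N)),
            Gamma=np.eye(N), D=np.zeros((N, N)), W=np.eye(N),
            U_tilde=np.zeros((N, N)), U=-0.1 * np.eye(N),
            theta_vec=np.full(N, 0.01),
        )
        state = NetworkState(t=0.0, V=np.full(N, 0.05), r=np.zeros(N))
        with pytest.raises(RunawayExcitationError):
            process_spikes_dendritic(state, spec)

    def test_batched_and_single_processing_agree(self, small_dendritic_net, rng):
        spec = small_dendritic_net
        M = 7
        # V must lie in the coding-error subspace (rows of Gamma^T)
        V = spec.Gamma.T @ rng.standard_normal((spec.J, M))
        V *= 2.0 * spec.theta_vec.max() / np.abs(V).max()
        r = np.zeros((spec.N, M))
        batch = NetworkState(t=0.0, V=V.copy(), r=r.copy())
        _, counts = process_spikes_dendritic(batch, spec)
        for m in range(M):
            single = NetworkState(t=0.0, V=V[:, m].copy(), r=r[:, m].copy())
            _, spikes = process_spikes_dendritic(single, spec)
            assert len(spikes) == counts[m]
            assert np.allclose(single.V, batch.V[:, m])
            assert np.allclose(single.r, batch.r[:, m])


class TestRunNetwork:
    def test_zero_input_zero_state_stays_silent(self, small_dendritic_net, dendritic_params):
        trace = run_network(small_dendritic_net, None, 0.1, dendritic_params)
        assert trace.spike_log.shape == (0, 2)

    def test_noise_driven_run_is_seed_deterministic(self, rng):
        params = NeuronParams.saturating(
            20.0, 10.0, theta=0.1, V_r=0.54 * 0.1, sigma_eta=0.05, dt=1e-3
        )
        spec = make_saturating_network(40, params, rng, g=1.5)
        traces = [
            run_network(
                spec, None, 1.0, params,
                rng=np.random.default_rng(7), scheme="euler", record_r_every=100,
            )
            for _ in range(2)
        ]
        assert np.array_equal(traces[0].spike_log, traces[1].spike_log)
        assert np.array_equal(traces[0].r, traces[1].r)

    def test_dt_refinement_converges(self, rng):
        """Halving dt changes the decoded noiseless trajectory by < 5%."""
        decoded = {}
        for dt in (1e-3, 5e-4):
            params = NeuronParams.dendritic(10.0, 10.0, 2.0, dt=dt)
            spec_rng = np.random.default_rng(3)
            from csnets.topology import make_dendritic_network

            spec = make_dendritic_network(120, 3, params, spec_rng, p=1.0, g=1.0, gamma_s=0.03)
            amp = np.array([0.8, 0.5, 0.9])

            def input_fn(t):
                return amp * np.sin(2 * np.pi * t / 3.0)

            state = NetworkState.zeros(spec.N)
            n = int(round(3.0 / dt))
            xs = np.empty((n, 3))
            for k in range(n):
                step_dendritic(state, spec, input_fn(state.t), params)
                xs[k] = decode_dendritic(spec.Gamma, state.r)
            decoded[dt] = xs
        a, b = decoded[1e-3], decoded[5e-4][1::2]
        rel = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))
        assert rel < 0.05
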