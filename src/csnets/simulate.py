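"""Time-grid simulation of both CSN variants.

The smooth part of the dynamics is advanced per grid step with classical
4th-order Runge-Kutta (or Euler; Euler-Maruyama whenever membrane white
noise is on), after which threshold crossings are processed at the grid
point:

* saturating variant — every neuron with ``V > theta/2`` emits exactly one
  spike: ``V -= theta``, ``r += 1``.  The encoded signal
  ``x = V + theta*r`` is therefore continuous across spikes.
* dendritic variant — fast somatic couplings act without delay, so spikes
  are processed sequentially: repeatedly pick the neuron with the highest
  ``V - theta_vec``; if above threshold, subtract the fast coupling column
  ``U[:, n]`` from all membrane potentials (the diagonal implements the
  self-reset) and increment ``r_n``.  Sequential processing preserves the
  spike ordering a finer-grained simulation would produce and prevents
  redundant simultaneous spikes of neurons coding for similar features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from numba import njit

from .topology import NetworkSpec, NeuronParams

__all__ = [
    "NetworkState",
    "SimulationTrace",
    "step_saturating",
    "step_dendritic",
    "process_spikes_dendritic",
    "run_network",
    "decode_saturating",
    "decode_dendritic",
]


class RunawayExcitationError(RuntimeError):
    """Raised when the sequential spike loop exceeds its iteration cap."""


@dataclass
class NetworkState:
    """Time-varying state: membrane potentials, synaptic currents, spikes.

    ``V`` and ``r`` may be 1-D ``(N,)`` or 2-D ``(N, M)`` for a batch of M
    independent replicas (used for mental-exploration rollouts; the spike
    log is only kept for 1-D states).
    """

    t: float
    V: np.ndarray
    r: np.ndarray
    spike_times: list = field(default_factory=list)
    spike_ids: list = field(default_factory=list)

    @classmethod
    def zeros(cls, N: int, M: Optional[int] = None) -> "NetworkState":
        shape = (N,) if M is None else (N, M)
        return cls(t=0.0, V=np.zeros(shape), r=np.zeros(shape))

    @classmethod
    def random(
        cls,
        spec: "NetworkSpec",
        params: "NeuronParams",
        rng: np.random.Generator,
        x_scale: float = 0.5,
    ) -> "NetworkState":
        """State seeding a random encoded signal of magnitude ``x_scale``.

        The rest state is a fixed point of the encoded dynamics, so
        training from it would never elicit activity.  Here a random
        continuous signal ``x0`` is drawn and mapped onto (V, r) through
        the coding relations (``r >= 0`` is enforced by rectification, as
        in the decoding approximations the networks are built on).
        """
        if spec.variant == "saturating":
            x0 = rng.normal(0.0, x_scale, size=spec.N)
            r0 = np.maximum(x0, 0.0) / params.theta
            V0 = np.minimum(x0, 0.0) + rng.uniform(
                -params.theta / 2, params.theta / 2, size=spec.N
            )
            return cls(t=0.0, V=V0, r=r0)
        x0 = rng.normal(0.0, x_scale, size=spec.J)
        G = spec.Gamma
        y = np.linalg.solve(G @ G.T, x0)
        r0 = np.maximum(G.T @ y, 0.0)
        # V must stay in the row space of Gamma^T (the coding-error
        # subspace): orthogonal components are never produced by the
        # dynamics and would destabilize the fast spike interactions.
        e0 = rng.standard_normal(spec.J)
        V0 = G.T @ e0
        peak = np.max(np.abs(V0) / spec.theta_vec)
        if peak > 0:
            V0 *= 0.9 / peak
        return cls(t=0.0, V=V0, r=r0)

    def spike_log(self) -> np.ndarray:
        """Spike events as an array of (time_s, neuron_id) rows."""
        if not self.spike_times:
            return np.empty((0, 2))
        t = np.concatenate([np.full(len(i), s) for s, i in zip(self.spike_times, self.spike_ids)])
        n = np.concatenate(self.spike_ids)
        return np.column_stack([t, n])

    def n_spikes(self) -> int:
        return int(sum(len(i) for i in self.spike_ids))


@dataclass
class SimulationTrace:
    """Recorded history of one run (decimated where requested)."""

    times: np.ndarray
    spike_log: np.ndarray  # (n_events, 2): time_s, neuron_id
    V: Optional[np.ndarray] = None
    r: Optional[np.ndarray] = None
    record_every: int = 1
    inputs: Optional[np.ndarray] = None

    def save_spikes(self, path) -> None:
        np.savetxt(path, self.spike_log, fmt="%.6f %d", header="time_s neuron_id")


def decode_saturating(V: np.ndarray, r: np.ndarray, theta: float) -> np.ndarray:
    """Directly encoded continuous signal ``x = V + theta * r``."""
    return V + theta * r


def decode_dendritic(Gamma: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Distributedly encoded continuous signal ``x ~= Gamma @ r``."""
    return Gamma @ r


# ---------------------------------------------------------------------------
# smooth vector fields


def _sat_dV(V, r, spec, params, I_e):
    drive = spec.A @ np.tanh(params.gamma * r)
    dV = -params.lambda_V * V + drive + params.V_r * params.lambda_s * r
    if I_e is not None:
        dV = dV + I_e
    return dV


def _dendr_dV(V, r, spec, params, I_soma):
    # The somatic drive factors through the decoder: D = Gamma^T A (kept
    # current by the recurrent learning rule, which is rank-1 in J x J) and
    # U~ = a Gamma^T Gamma + mu lambda_s I, so the expensive N x N and
    # N x J products reduce to J-space operations sharing one Gamma @ r.
    pre = spec.Gamma @ r
    if spec.bias_b is not None:
        pre_b = pre + (spec.bias_b if pre.ndim == 1 else spec.bias_b[:, None])
    else:
        pre_b = pre
    slow = spec.A @ np.tanh(pre_b) + params.a * pre
    dV = -params.lambda_V * V + spec.Gamma.T @ slow
    if params.mu > 0:
        dV += (params.mu * params.lambda_s) * r
    if I_soma is not None:
        dV = dV + I_soma
    return dV


def _advance_smooth(state, spec, params, I_e, rng, scheme, dV_fn):
    """In-place smooth update of (V, r) over one step of params.dt."""
    dt = params.dt
    V, r = state.V, state.r
    ls = params.lambda_s
    if params.sigma_eta > 0 or scheme == "euler":
        V += dt * dV_fn(V, r, spec, params, I_e)
        if params.sigma_eta > 0:
            V += params.sigma_eta * np.sqrt(dt) * rng.standard_normal(V.shape)
        r *= 1.0 - ls * dt
    else:  # classical RK4 on the joint (V, r) field; r decays linearly
        k1V = dV_fn(V, r, spec, params, I_e)
        k1r = -ls * r
        k2V = dV_fn(V + 0.5 * dt * k1V, r + 0.5 * dt * k1r, spec, params, I_e)
        k2r = -ls * (r + 0.5 * dt * k1r)
        k3V = dV_fn(V + 0.5 * dt * k2V, r + 0.5 * dt * k2r, spec, params, I_e)
        k3r = -ls * (r + 0.5 * dt * k2r)
        k4V = dV_fn(V + dt * k3V, r + dt * k3r, spec, params, I_e)
        k4r = -ls * (r + dt * k3r)
        V += (dt / 6.0) * (k1V + 2 * k2V + 2 * k3V + k4V)
        r += (dt / 6.0) * (k1r + 2 * k2r + 2 * k3r + k4r)
    state.t += dt


def _check_finite(V):
    # a non-finite entry poisons the sum, so one reduction suffices
    if not np.isfinite(V.sum()):
        bad = int(np.argwhere(~np.isfinite(V))[0][0])
        raise FloatingPointError(f"non-finite membrane potential, first at neuron {bad}")


# ---------------------------------------------------------------------------
# saturating variant


@njit(cache=True)
def _sat_euler_block(V, r, A, w_o, I_block, noise_block, z_out,
                     lam_V, Vr_ls, gamma, theta, ls, dt, sig_sqdt):
    """Euler(-Maruyama) stepping of the saturating network over a block.

    Matches the per-step arithmetic of :func:`step_saturating` with the
    Euler scheme; records the readout ``z = w_o @ tanh(gamma r)`` at every
    step.  Spike events update (V, r) but are not logged (used by the
    static-reservoir fast path where only outputs are read out).
    """
    n, N = I_block.shape
    K = w_o.shape[0]
    half_theta = 0.5 * theta
    decay = 1.0 - ls * dt
    for k in range(n):
        r_t = np.tanh(gamma * r)
        for c in range(K):
            acc = 0.0
            for i in range(N):
                acc += w_o[c, i] * r_t[i]
            z_out[k, c] = acc
        drive = A @ r_t
        for i in range(N):
            V[i] += dt * (-lam_V * V[i] + drive[i] + Vr_ls * r[i] + I_block[k, i])
        if sig_sqdt > 0.0:
            for i in range(N):
                V[i] += sig_sqdt * noise_block[k, i]
        for i in range(N):
            r[i] *= decay
            if V[i] > half_theta:
                V[i] -= theta
                r[i] += 1.0
    return V[0]


def step_saturating(
    state: NetworkState,
    spec: NetworkSpec,
    I_e: Optional[np.ndarray],
    params: NeuronParams,
    rng: Optional[np.random.Generator] = None,
    scheme: str = "rk4",
) -> NetworkState:
    """One grid step of the saturating-synapse network (in place).

    Smooth update of ``dV/dt = -lambda_V V + A tanh(gamma r)
    + V_r lambda_s r + I_e`` and ``dr/dt = -lambda_s r``, then every neuron
    with ``V > theta/2`` spikes once (``V -= theta``, ``r += 1``).
    """
    _advance_smooth(state, spec, params, I_e, rng, scheme, _sat_dV)
    _check_finite(state.V)
    spiking = state.V > 0.5 * params.theta
    if spiking.any():
        state.V[spiking] -= params.theta
        state.r[spiking] += 1.0
        if state.V.ndim == 1:
            state.spike_times.append(state.t)
            state.spike_ids.append(np.flatnonzero(spiking))
    return state


# ---------------------------------------------------------------------------
# dendritic variant


@njit(cache=True)
def _spike_loop(V, r, U, theta, always_reset, max_iter):
    """Sequential highest-potential spike processing (1-D state)."""
    N = V.shape[0]
    spikes = np.empty(max_iter, np.int64)
    count = 0
    while count < max_iter:
        best = 0
        bestv = V[0] - theta[0]
        for i in range(1, N):
            d = V[i] - theta[i]
            if d > bestv:
                bestv = d
                best = i
        if bestv <= 0.0:
            return spikes[:count], False
        for i in range(N):
            V[i] -= U[i, best]
        if always_reset:
            V[best] = -theta[best]
        r[best] += 1.0
        spikes[count] = best
        count += 1
    return spikes[:count], True


@njit(cache=True)
def _spike_loop_batched(V, r, U, theta, always_reset, max_iter):
    """Sequential spike processing per column of a (N, M) state batch."""
    N, M = V.shape
    counts = np.zeros(M, np.int64)
    overflow = False
    for m in range(M):
        while counts[m] < max_iter:
            best = 0
            bestv = V[0, m] - theta[0]
            for i in range(1, N):
                d = V[i, m] - theta[i]
                if d > bestv:
                    bestv = d
                    best = i
            if bestv <= 0.0:
                break
            for i in range(N):
                V[i, m] -= U[i, best]
            if always_reset:
                V[best, m] = -theta[best]
            r[best, m] += 1.0
            counts[m] += 1
        else:
            overflow = True
    return counts, overflow


def process_spikes_dendritic(state: NetworkState, spec: NetworkSpec):
    """Apply the sequential fast-interaction spike scheme at a grid point.

    Returns ``(state, new_spike_ids)``.  Under ``reset_mode ==
    "always_minus_theta"`` the spiking neuron is reset to ``-theta_n``
    regardless of prior fast input; otherwise the reset is carried by the
    diagonal of ``U`` (reset by ``2 theta_n``).
    """
    always = spec.reset_mode == "always_minus_theta"
    cap = 10 * spec.N
    if state.V.ndim == 1:
        spikes, overflow = _spike_loop(
            state.V, state.r, spec.U, spec.theta_vec, always, cap
        )
        if overflow:
            raise RunawayExcitationError(
                f"more than {cap} spikes in one step at t={state.t:.4f}s"
            )
        if len(spikes):
            state.spike_times.append(state.t)
            state.spike_ids.append(spikes.copy())
        return state, spikes
    counts, overflow = _spike_loop_batched(
        state.V, state.r, spec.U, spec.theta_vec, always, cap
    )
    if overflow:
        raise RunawayExcitationError(f"spike cap {cap} exceeded in batch step")
    return state, counts


def step_dendritic(
    state: NetworkState,
    spec: NetworkSpec,
    I_e: Optional[np.ndarray],
    params: NeuronParams,
    rng: Optional[np.random.Generator] = None,
    scheme: str = "rk4",
    I_soma: Optional[np.ndarray] = None,
) -> NetworkState:
    """One grid step of the nonlinear-dendrite network (in place).

    ``I_e`` is the J-dimensional external input entering the somata through
    ``Gamma.T``; alternatively a pre-projected N-dimensional ``I_soma`` may
    be supplied directly.
    """
    if I_soma is None and I_e is not None:
        I_soma = spec.Gamma.T @ I_e
    _advance_smooth(state, spec, params, I_soma, rng, scheme, _dendr_dV)
    _check_finite(state.V)
    process_spikes_dendritic(state, spec)
    return state


# ---------------------------------------------------------------------------
# driver


def run_network(
    spec: NetworkSpec,
    input_fn: Union[None, Callable[[float], np.ndarray], np.ndarray],
    duration: float,
    params: NeuronParams,
    rng: Optional[np.random.Generator] = None,
    scheme: str = "rk4",
    state: Optional[NetworkState] = None,
    record_V_every: int = 0,
    record_r_every: int = 0,
) -> SimulationTrace:
    """Simulate for ``duration`` seconds on the grid defined by params.dt.

    ``input_fn`` may be None, a callable of time, or a pre-tabulated
    ``(n_steps, dim)`` array (dim = N for saturating, J for dendritic).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.sigma_eta > 0 and rng is None:
        raise ValueError("rng required when sigma_eta > 0")
    n_steps = int(round(duration / params.dt))
    if state is None:
        state = NetworkState.zeros(spec.N)
    step = step_saturating if spec.variant == "saturating" else step_dendritic
    tab = input_fn if isinstance(input_fn, np.ndarray) else None
    V_hist, r_hist, times = [], [], []
    for k in range(n_steps):
        if tab is not None:
            I_e = tab[k]
        elif input_fn is not None:
            I_e = input_fn(state.t)
        else:
            I_e = None
        step(state, spec, I_e, params, rng, scheme=scheme)
        if record_V_every and (k + 1) % record_V_every == 0:
            V_hist.append(state.V.copy())
        if record_r_every and (k + 1) % record_r_every == 0:
            r_hist.append(state.r.copy())
            times.append(state.t)
    rec = record_r_every or record_V_every or 1
    if not times:
        times = (np.arange(n_steps) + 1) * params.dt
    return SimulationTrace(
        times=np.asarray(times),
        spike_log=state.spike_log(),
        V=np.array(V_hist) if V_hist else None,
        r=np.array(r_hist) if r_hist else None,
        record_every=rec,
    )
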