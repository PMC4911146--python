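"""Readouts and online learning (recursive least squares / FORCE).

Outputs are linear combinations of the same saturated synaptic or dendritic
currents that somata inside the network receive:

* saturating variant: ``z = w_o @ tanh(gamma * r)`` (N regressors),
* dendritic variant:  ``z = w_o @ tanh(b + Gamma @ r)`` (J regressors).

Output weights are learned online with recursive least squares; ``P`` is a
running estimate of the inverse correlation matrix of the regressors and
acts as a per-synapse learning rate.  With output feedback this is FORCE
learning: the output is fed back during training, and because it is held
close to the target from the start, the feedback loop remains stable.  The
feedback loop can equivalently be absorbed into the recurrent couplings
(``A`` for saturating synapses, dendro-somatic ``D`` for dendrites); both
interpretations perform the same weight updates and inject identical
currents into the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .simulate import NetworkState, _sat_euler_block, step_dendritic, step_saturating
from .topology import NetworkSpec, NeuronParams

__all__ = [
    "ReadoutLearner",
    "FeedbackSpec",
    "activations",
    "readout",
    "rls_update",
    "force_recurrent_update",
    "train",
    "run_autonomous",
    "TrainingTrace",
]


@dataclass
class ReadoutLearner:
    """Output weights and RLS state.

    ``w_o`` starts at zero and ``P`` at ``I / alpha``; ``alpha`` acts as a
    ridge regularizer (equivalently, ``1/alpha`` is the initial learning
    rate).  Updates happen every ``delta_t_update`` seconds of simulated
    time, which must be an integer multiple of the integration step.
    """

    w_o: np.ndarray
    P: np.ndarray
    alpha: float
    delta_t_update: float = 0.01
    e: Optional[np.ndarray] = None
    n_updates: int = 0

    @classmethod
    def init(
        cls, K_out: int, n_regressors: int, alpha: float, delta_t_update: float = 0.01
    ) -> "ReadoutLearner":
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        return cls(
            w_o=np.zeros((K_out, n_regressors)),
            P=np.eye(n_regressors) / alpha,
            alpha=alpha,
            delta_t_update=delta_t_update,
        )


@dataclass
class FeedbackSpec:
    """Static feedback weights and the training-time mixing coefficient.

    During training the signal fed back is ``mix * z + (1 - mix) * F``;
    ``mix = 1`` is pure output feedback (the FORCE default), smaller values
    blend in the target, which helps when early outputs are too erroneous
    to be useful feedback.  During autonomous recall feedback is always the
    pure output.
    """

    w_fb: np.ndarray
    mix: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.mix <= 1.0):
            raise ValueError("mix must lie in [0, 1]")


def activations(spec: NetworkSpec, params: NeuronParams, r: np.ndarray) -> np.ndarray:
    """Saturated synaptic (length N) or dendritic (length J) inputs r~."""
    if spec.variant == "saturating":
        return np.tanh(params.gamma * r)
    pre = spec.Gamma @ r
    if spec.bias_b is not None:
        pre = pre + (spec.bias_b if pre.ndim == 1 else spec.bias_b[:, None])
    return np.tanh(pre)


def readout(w_o: np.ndarray, r_tilde: np.ndarray) -> np.ndarray:
    """Linear readout ``z = w_o @ r_tilde``."""
    return w_o @ r_tilde


@njit(cache=True)
def _rls_core(P, r_tilde, symmetrize):
    """Fused rank-one downdate of P; returns (denom, gain = P_new @ r~)."""
    Pr = P @ r_tilde
    denom = 1.0 + float(r_tilde @ Pr)
    if denom <= 0.0:
        return denom, Pr
    inv = 1.0 / denom
    B = P.shape[0]
    for i in range(B):
        pi = Pr[i] * inv
        for j in range(B):
            P[i, j] -= pi * Pr[j]
    if symmetrize:
        # rank-one updates preserve symmetry up to rounding; periodic
        # re-symmetrization stops drift accumulating over 1e5+ updates
        for i in range(B):
            for j in range(i):
                m = 0.5 * (P[i, j] + P[j, i])
                P[i, j] = m
                P[j, i] = m
    return denom, Pr * inv


def rls_update(
    learner: ReadoutLearner,
    r_tilde: np.ndarray,
    F: np.ndarray,
    z: np.ndarray,
) -> ReadoutLearner:
    """One recursive-least-squares step (in place).

    The error ``e = z - F`` uses the pre-update weights; ``P`` is updated
    first (rank-one Sherman-Morrison), then the weights move along the
    updated gain ``P_new @ r_tilde``.  ``P`` is re-symmetrized every 50
    updates to keep it positive definite over long runs.
    """
    e = np.atleast_1d(z - F)
    denom, gain = _rls_core(
        learner.P, np.ascontiguousarray(r_tilde), learner.n_updates % 50 == 49
    )
    if denom <= 0.0:
        raise FloatingPointError(
            f"RLS denominator {denom:.3e} <= 0: P lost positive definiteness"
        )
    learner.w_o -= np.outer(e, gain)
    learner.e = e
    learner.n_updates += 1
    return learner


def force_recurrent_update(
    spec: NetworkSpec,
    learner: ReadoutLearner,
    feedback: FeedbackSpec,
    r_tilde: np.ndarray,
    gain: Optional[np.ndarray] = None,
) -> NetworkSpec:
    """Absorb the feedback-loop weight update into the recurrence (in place).

    Uses the last error stored on the learner.  For saturating synapses the
    slow coupling matrix ``A`` moves by ``-outer(w_fb @ e, P @ r~)``; for
    nonlinear dendrites the dendro-somatic couplings move by
    ``-outer(Gamma.T @ (w_fb @ e), P @ r~)``.  The static feedback weights
    act as per-neuron learning rates.
    """
    if learner.e is None:
        raise RuntimeError("no error available; call rls_update first")
    if gain is None:
        gain = learner.P @ r_tilde
    fb_err = feedback.w_fb @ learner.e
    if spec.variant == "saturating":
        spec.A -= np.outer(fb_err, gain)
    else:
        # the dendro-somatic update factors as Gamma^T (rank-1 in J x J):
        # keep the slow coupling A current (the simulator's factored drive
        # uses it) alongside the explicit D for inspection
        spec.A -= np.outer(fb_err, gain)
        spec.D -= np.outer(spec.Gamma.T @ fb_err, gain)
    return spec


@dataclass
class TrainingTrace:
    """Per-update error magnitudes and per-step outputs from training."""

    times: np.ndarray
    error_norms: np.ndarray
    z: np.ndarray  # (n_steps, K_out)


def _soma_projector(spec: NetworkSpec):
    """Map input-space currents (beta-indexed) to per-soma currents."""
    if spec.variant == "saturating":
        return None  # identity
    return spec.Gamma.T.copy()


def train(
    spec: NetworkSpec,
    params: NeuronParams,
    task,
    learner: ReadoutLearner,
    feedback: Optional[FeedbackSpec] = None,
    mode: str = "feedback",
    rng: Optional[np.random.Generator] = None,
    scheme: str = "rk4",
    state: Optional[NetworkState] = None,
    max_error: float = 1e6,
):
    """FORCE/RLS training over one task episode (weights learned in place).

    ``mode`` is one of:

    * ``"readout"`` — plain RLS on the output weights, no feedback
      (reservoir computing with a static network),
    * ``"feedback"`` — FORCE with an explicit output-feedback loop,
    * ``"recurrent"`` — the same learning absorbed into the recurrent
      couplings (``A`` or ``D``); no separate feedback pathway exists.

    The task supplies the time grid (its ``dt`` must equal ``params.dt``),
    the input channels and the target channels.  Returns
    ``(spec, learner, state, trace)`` with the end-of-training network
    state, so recall can continue seamlessly.
    """
    if mode not in ("readout", "feedback", "recurrent"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "readout" and feedback is None:
        raise ValueError(f"mode {mode!r} requires a FeedbackSpec")
    dt = params.dt
    if abs(task.dt - dt) > 1e-12:
        raise ValueError("task grid step must equal params.dt")
    n_update = int(round(learner.delta_t_update / dt))
    if abs(n_update * dt - learner.delta_t_update) > 1e-9:
        raise ValueError("delta_t_update must be an integer multiple of dt")
    targets = np.atleast_2d(task.targets.T).T  # (T, K_out)
    inputs = task.inputs
    n_steps = targets.shape[0]
    if state is None:
        state = NetworkState.zeros(spec.N)
    proj = _soma_projector(spec)
    w_in = spec.w_in
    base = None
    if inputs is not None and w_in is not None:
        base = inputs @ w_in.T  # (T, beta)
        if proj is not None:
            base = base @ spec.Gamma  # (T, N): (Gamma.T @ I_e).T
    wfb_soma = None
    if mode == "feedback":
        wfb_soma = feedback.w_fb if proj is None else proj @ feedback.w_fb
    step = step_saturating if spec.variant == "saturating" else step_dendritic
    z_hist = np.empty((n_steps, learner.w_o.shape[0]))
    upd_times, upd_errs = [], []
    if (
        mode == "readout"
        and spec.variant == "saturating"
        and (params.sigma_eta > 0 or scheme == "euler")
    ):
        # static-reservoir fast path: the network evolution is independent
        # of the learned weights, so whole update intervals are advanced in
        # one compiled block (identical stepping; spikes are not logged)
        sig_sqdt = params.sigma_eta * np.sqrt(dt)
        dummy = np.zeros((1, 1))
        for k0 in range(0, n_steps, n_update):
            k1 = min(k0 + n_update, n_steps)
            I_block = base[k0:k1] if base is not None else np.zeros((k1 - k0, spec.N))
            noise = (
                rng.standard_normal((k1 - k0, spec.N)) if params.sigma_eta > 0 else dummy
            )
            _sat_euler_block(
                state.V, state.r, spec.A, learner.w_o,
                np.ascontiguousarray(I_block), noise, z_hist[k0:k1],
                params.lambda_V, params.V_r * params.lambda_s, params.gamma,
                params.theta, params.lambda_s, dt, sig_sqdt,
            )
            state.t += (k1 - k0) * dt
            if k1 - k0 == n_update:
                r_tilde = activations(spec, params, state.r)
                z = learner.w_o @ r_tilde
                rls_update(learner, r_tilde, targets[k1 - 1], z)
                err = float(np.linalg.norm(learner.e))
                if not np.isfinite(err) or err > max_error:
                    raise FloatingPointError(
                        f"training error diverged (|e|={err:.3e}) at t={state.t:.2f}s"
                    )
                upd_times.append(state.t)
                upd_errs.append(err)
        trace = TrainingTrace(np.asarray(upd_times), np.asarray(upd_errs), z_hist)
        return spec, learner, state, trace
    for k in range(n_steps):
        r_tilde = activations(spec, params, state.r)
        z = learner.w_o @ r_tilde
        z_hist[k] = z
        I_soma = base[k] if base is not None else None
        if mode == "feedback":
            fb = feedback.mix * z + (1.0 - feedback.mix) * targets[k]
            fb_current = wfb_soma @ fb
            I_soma = fb_current if I_soma is None else I_soma + fb_current
        if spec.variant == "saturating":
            step(state, spec, I_soma, params, rng, scheme=scheme)
        else:
            step(state, spec, None, params, rng, scheme=scheme, I_soma=I_soma)
        if (k + 1) % n_update == 0:
            r_tilde = activations(spec, params, state.r)
            z = learner.w_o @ r_tilde
            rls_update(learner, r_tilde, targets[k], z)
            if mode == "recurrent":
                # Sherman-Morrison gain of this update, recomputed cheaply
                force_recurrent_update(
                    spec, learner, feedback, r_tilde, gain=learner.P @ r_tilde
                )
            err = float(np.linalg.norm(learner.e))
            if not np.isfinite(err) or err > max_error:
                raise FloatingPointError(
                    f"training error diverged (|e|={err:.3e}) at t={state.t:.2f}s"
                )
            upd_times.append(state.t)
            upd_errs.append(err)
    trace = TrainingTrace(np.asarray(upd_times), np.asarray(upd_errs), z_hist)
    return spec, learner, state, trace


def run_autonomous(
    spec: NetworkSpec,
    params: NeuronParams,
    learner: ReadoutLearner,
    feedback: Optional[FeedbackSpec],
    duration: float,
    mode: str = "feedback",
    inputs: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    scheme: str = "rk4",
    state: Optional[NetworkState] = None,
):
    """Run with frozen weights; feedback (if any) is the pure output.

    ``inputs`` is an optional pre-tabulated ``(n_steps, K_in)`` array of
    external input channels weighted through ``spec.w_in``.  Returns
    ``(times, z, state)``; spikes accumulate on the state's log.
    """
    dt = params.dt
    n_steps = int(round(duration / dt))
    if state is None:
        state = NetworkState.zeros(spec.N)
    proj = _soma_projector(spec)
    base = None
    if inputs is not None and spec.w_in is not None:
        base = inputs @ spec.w_in.T
        if proj is not None:
            base = base @ spec.Gamma
    wfb_soma = None
    if mode == "feedback" and feedback is not None:
        wfb_soma = feedback.w_fb if proj is None else proj @ feedback.w_fb
    step = step_saturating if spec.variant == "saturating" else step_dendritic
    z_hist = np.empty((n_steps, learner.w_o.shape[0]))
    if (
        mode == "readout"
        and wfb_soma is None
        and spec.variant == "saturating"
        and (params.sigma_eta > 0 or scheme == "euler")
    ):
        sig_sqdt = params.sigma_eta * np.sqrt(dt)
        dummy = np.zeros((1, 1))
        chunk = 5000
        for k0 in range(0, n_steps, chunk):
            k1 = min(k0 + chunk, n_steps)
            I_block = base[k0:k1] if base is not None else np.zeros((k1 - k0, spec.N))
            noise = (
                rng.standard_normal((k1 - k0, spec.N)) if params.sigma_eta > 0 else dummy
            )
            _sat_euler_block(
                state.V, state.r, spec.A, learner.w_o,
                np.ascontiguousarray(I_block), noise, z_hist[k0:k1],
                params.lambda_V, params.V_r * params.lambda_s, params.gamma,
                params.theta, params.lambda_s, dt, sig_sqdt,
            )
            state.t += (k1 - k0) * dt
        times = (np.arange(n_steps) + 1) * dt + (state.t - n_steps * dt)
        return times, z_hist, state
    for k in range(n_steps):
        r_tilde = activations(spec, params, state.r)
        z = learner.w_o @ r_tilde
        z_hist[k] = z
        I_soma = base[k] if base is not None else None
        if wfb_soma is not None:
            fb_current = wfb_soma @ z
            I_soma = fb_current if I_soma is None else I_soma + fb_current
        if spec.variant == "saturating":
            step(state, spec, I_soma, params, rng, scheme=scheme)
        else:
            step(state, spec, None, params, rng, scheme=scheme, I_soma=I_soma)
    times = (np.arange(n_steps) + 1) * dt + (state.t - n_steps * dt)
    return times, z_hist, state
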