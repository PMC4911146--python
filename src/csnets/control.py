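"""Mental exploration and path-integral stochastic optimal control.

The controller repeatedly (every ``Delta`` seconds) simulates M future
rollouts of a world model under fresh exploratory white-noise forces with
zero deterministic control ("mental exploration"), scores each rollout by
its integrated reward (here the pendulum height, so inversion is optimal),
and applies the reward-softmax-weighted average of the initial noise
segments as the control::

    u = sum_i softmax(lambda_c * R)_i * mean(xi_i over [0, delta])

The world model is either the ground-truth plant (an upper bound on model
quality) or a spiking network trained to imitate the plant from motor
babbling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .learning import FeedbackSpec, ReadoutLearner, activations
from .simulate import NetworkState, step_dendritic
from .tasks import C_OMEGA0, OMEGA0_SQ, PendulumState, pendulum_step
from .topology import NetworkSpec, NeuronParams

__all__ = [
    "ControlConfig",
    "ControlPlan",
    "GroundTruthPendulumModel",
    "PCSNWorldModel",
    "mental_explore",
    "path_integral_control",
    "control_loop",
]


@dataclass
class ControlConfig:
    """Path-integral controller settings.

    M rollouts of horizon ``T_r`` seconds are drawn every replanning
    interval ``Delta``; the applied control is the softmax-weighted average
    of the noise over the initial window ``delta`` (requires
    ``Delta < delta <= T_r``).  ``lambda_c`` weights the time-integrated
    reward (units of seconds) in the softmax; the default 10/s is the
    per-sample weighting 0.01 applied to reward sums on a 1 ms grid.
    ``q`` is the exploration/plant noise intensity (1/s^3).  Because
    rollout rewards from one state differ only slightly, the controller
    relies on frequent replanning (small ``Delta``) to average out the
    sampling noise of the weighted estimate.
    """

    M: int = 200
    T_r: float = 1.0
    delta: float = 0.1
    Delta: float = 0.01
    lambda_c: float = 10.0
    rollout_dt: float = 0.005
    q: float = 1.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not (self.Delta < self.delta <= self.T_r):
            raise ValueError("need Delta < delta <= T_r")


@dataclass
class ControlPlan:
    """One replanning cycle: sampled noise, rewards, weights, control."""

    xis: np.ndarray  # (M, T)
    rewards: np.ndarray  # (M,)
    weights: np.ndarray  # (M,), non-negative, sums to 1
    u: float


class GroundTruthPendulumModel:
    """The plant itself used as world model (vectorized over rollouts)."""

    def __init__(self, dt: float):
        self.dt = dt
        self.phi = 0.0
        self.omega = 0.0

    def set_state(self, state: PendulumState) -> None:
        self.phi = float(state.phi)
        self.omega = float(state.omega)

    def rollout(self, xis: np.ndarray) -> np.ndarray:
        """Heights y(t) for each noise realization, shape (M, T)."""
        M, T = xis.shape
        phi = np.full(M, self.phi)
        omega = np.full(M, self.omega)
        y = np.empty((M, T))
        dt = self.dt
        for k in range(T):
            dom = -OMEGA0_SQ * np.sin(phi) - C_OMEGA0 * omega + xis[:, k]
            phi = phi + dt * omega
            omega = omega + dt * dom
            y[:, k] = -np.cos(phi)
        return y


class PCSNWorldModel:
    """A trained spiking network used as the pendulum world model.

    The network was trained with output feedback to imitate the pendulum's
    (x, y, omega) response to a white-noise force received as input.  For
    rollouts it runs autonomously (feedback = own outputs) driven by the
    exploratory noise.  Before each rollout batch the feedback channels are
    clamped to the observed plant state for a short washout so the
    enslaved network state matches the plant — the network analogue of
    initializing the model through sensory input.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        params: NeuronParams,
        learner: ReadoutLearner,
        feedback: FeedbackSpec,
        dt: float,
        clamp_duration: float = 0.2,
    ):
        self.spec = spec
        self.params = params
        self.learner = learner
        self.feedback = feedback
        self.dt = dt
        self.clamp_duration = clamp_duration
        self._wfb_soma = spec.Gamma.T @ feedback.w_fb  # (N, 3)
        self._win_soma = (spec.Gamma.T @ spec.w_in).ravel()  # (N,)
        self._state = NetworkState.zeros(spec.N)
        # rollout integration params (may use a coarser grid than training)
        self._roll_params = NeuronParams(
            lambda_V=params.lambda_V,
            lambda_s=params.lambda_s,
            lambda_x=params.lambda_x,
            theta=params.theta,
            V_r=params.V_r,
            gamma=params.gamma,
            mu=params.mu,
            sigma_eta=0.0,
            dt=dt,
        )

    def set_state(self, state: PendulumState) -> None:
        sensed = np.array([state.x, state.y, state.omega])
        clamp_current = self._wfb_soma @ sensed
        n = int(round(self.clamp_duration / self.dt))
        for _ in range(n):
            step_dendritic(
                self._state, self.spec, None, self._roll_params,
                scheme="euler", I_soma=clamp_current,
            )

    def rollout(self, xis: np.ndarray) -> np.ndarray:
        """Predicted heights y(t) per noise realization, shape (M, T)."""
        M, T = xis.shape
        batch = NetworkState(
            t=0.0,
            V=np.repeat(self._state.V[:, None], M, axis=1),
            r=np.repeat(self._state.r[:, None], M, axis=1),
        )
        y = np.empty((M, T))
        for k in range(T):
            r_t = activations(self.spec, self._roll_params, batch.r)  # (J, M)
            z = self.learner.w_o @ r_t  # (3, M)
            I_soma = self._wfb_soma @ z + np.outer(self._win_soma, xis[:, k])
            step_dendritic(
                batch, self.spec, None, self._roll_params,
                scheme="euler", I_soma=I_soma,
            )
            y[:, k] = z[1]
        return y


def mental_explore(
    model,
    init_state: PendulumState,
    config: ControlConfig,
    rng: np.random.Generator,
):
    """Simulate M uncontrolled noise-driven futures from the current state.

    Returns ``(trajectories, xis)``; rollouts that diverge to non-finite
    values are dropped (rows removed from both arrays) with a warning.
    """
    n_steps = int(round(config.T_r / config.rollout_dt))
    xis = np.sqrt(config.q / config.rollout_dt) * rng.standard_normal(
        (config.M, n_steps)
    )
    model.set_state(init_state)
    ys = model.rollout(xis)
    ok = np.all(np.isfinite(ys), axis=1)
    if not ok.all():
        warnings.warn(f"excluded {int((~ok).sum())} diverged rollouts", stacklevel=2)
        ys, xis = ys[ok], xis[ok]
    if len(ys) == 0:
        raise RuntimeError("all rollouts diverged")
    return ys, xis


def path_integral_control(
    xis: np.ndarray, rewards: np.ndarray, config: ControlConfig
) -> ControlPlan:
    """Reward-softmax-weighted average of the initial noise segments.

    Weights ``w_i = exp(lambda_c R_i) / sum_j exp(lambda_c R_j)`` are
    computed stably by subtracting the maximum reward; the control is the
    weighted mean of each rollout's noise averaged over the first
    ``delta`` seconds, held constant over the replanning interval.
    """
    rewards = np.asarray(rewards, dtype=float)
    if len(rewards) == 0:
        raise ValueError("no valid rollouts")
    if not np.all(np.isfinite(rewards)):
        raise ValueError("rewards must be finite")
    logw = config.lambda_c * (rewards - rewards.max())
    w = np.exp(logw)
    w /= w.sum()
    n_delta = max(1, int(round(config.delta / config.rollout_dt)))
    xi_bar = xis[:, :n_delta].mean(axis=1)
    return ControlPlan(xis=xis, rewards=rewards, weights=w, u=float(w @ xi_bar))


def control_loop(
    model,
    config: ControlConfig,
    duration: float,
    rng: np.random.Generator,
    plant_state: Optional[PendulumState] = None,
    plant_dt: float = 0.005,
    reward_fn=None,
):
    """Alternate mental exploration, planning, and control application.

    Every ``Delta`` seconds: explore M futures from the plant's current
    state, score each by its integrated height ``R_i = int y_i dt``
    (``reward_fn`` may override), compute the path-integral control and
    apply it to the noisy plant for ``Delta``.  Returns a dict log with
    the plant trajectory, applied controls and per-cycle mean rewards.
    """
    if plant_state is None:
        plant_state = PendulumState(0.0, 0.0)
    n_cycles = int(round(duration / config.Delta))
    n_apply = max(1, int(round(config.Delta / plant_dt)))
    t_log, phi_log, y_log, u_log, reward_log = [], [], [], [], []
    t = 0.0
    for _ in range(n_cycles):
        ys, xis = mental_explore(model, plant_state, config, rng)
        if reward_fn is None:
            rewards = ys.sum(axis=1) * config.rollout_dt
        else:
            rewards = reward_fn(ys)
        plan = path_integral_control(xis, rewards, config)
        for _ in range(n_apply):
            xi = np.sqrt(config.q / plant_dt) * rng.standard_normal()
            plant_state = pendulum_step(plant_state, plan.u, xi, plant_dt)
            t += plant_dt
            t_log.append(t)
            phi_log.append(plant_state.phi)
            y_log.append(plant_state.y)
            u_log.append(plan.u)
        reward_log.append(float(rewards.mean()))
    return {
        "t": np.array(t_log),
        "phi": np.array(phi_log),
        "y": np.array(y_log),
        "u": np.array(u_log),
        "cycle_mean_reward": np.array(reward_log),
        "final_state": plant_state,
    }
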