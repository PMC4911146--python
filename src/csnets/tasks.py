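"""Benchmark input/target signal generators and the stochastic pendulum.

Every task used in the experiments is purely synthetic: periodic waveforms
(sine, sawtooth, camel-hump), a Lorenz teacher trajectory, stochastic
delayed-reaction trials, the instruction-switching signal set, and a noisy
pendulum plant for world-model learning and control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "TaskSignalBundle",
    "PendulumState",
    "periodic_target",
    "make_periodic_task",
    "lorenz_teacher",
    "delayed_reaction_trials",
    "instruction_task_signals",
    "pendulum_step",
    "simulate_pendulum",
    "OMEGA0_SQ",
    "C_OMEGA0",
]


@dataclass
class TaskSignalBundle:
    """Time-gridded input and target channels for one task episode."""

    t: np.ndarray
    inputs: Optional[np.ndarray]  # (T, K_in) or None
    targets: np.ndarray  # (T, K_out)
    name: str = ""
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self):
        self.targets = np.atleast_2d(self.targets.T).T
        if self.inputs is not None and len(self.inputs) != len(self.t):
            raise ValueError("input grid length mismatch")
        if len(self.targets) != len(self.t):
            raise ValueError("target grid length mismatch")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("non-finite target values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(len(self.t) * self.dt)

    def save_table(self, path) -> None:
        cols = [self.t]
        names = ["time_s"]
        if self.inputs is not None:
            cols += [self.inputs[:, k] for k in range(self.inputs.shape[1])]
            names += [f"input_{k}" for k in range(self.inputs.shape[1])]
        cols += [self.targets[:, k] for k in range(self.targets.shape[1])]
        names += [f"target_{k}" for k in range(self.targets.shape[1])]
        np.savetxt(path, np.column_stack(cols), header=" ".join(names))


# ---------------------------------------------------------------------------
# periodic patterns


def periodic_target(kind: str, t):
    """Periodic benchmark waveforms.

    * ``sine`` — amplitude 2, period 4*pi s: ``2 sin(t / 2s)``.
    * ``sawtooth`` — period 2 s, amplitude 10: rising ramp from -10 to
      +10 with a discontinuity at period boundaries (amplitude names the
      half-range, as for the sine).
    * ``camel`` — ``sin(t / 0.5s) + cos(t / 1s)``.
    """
    t = np.asarray(t, dtype=float)
    if kind == "sine":
        return 2.0 * np.sin(t / 2.0)
    if kind == "sawtooth":
        return 20.0 * np.mod(t / 2.0, 1.0) - 10.0
    if kind == "camel":
        return np.sin(t / 0.5) + np.cos(t / 1.0)
    raise ValueError(f"unknown periodic pattern {kind!r}")


def make_periodic_task(kind: str, duration: float, dt: float) -> TaskSignalBundle:
    t = np.arange(int(round(duration / dt))) * dt
    return TaskSignalBundle(
        t=t, inputs=None, targets=periodic_target(kind, t), name=kind
    )


# ---------------------------------------------------------------------------
# Lorenz teacher


@njit(cache=True)
def _lorenz_rk4(n_steps, h, x0, y0, z0, sigma, rho, beta):
    out = np.empty((n_steps, 3))
    x, y, z = x0, y0, z0
    for k in range(n_steps):
        k1x = sigma * (y - x)
        k1y = x * (rho - z) - y
        k1z = x * y - beta * z
        ax, ay, az = x + 0.5 * h * k1x, y + 0.5 * h * k1y, z + 0.5 * h * k1z
        k2x = sigma * (ay - ax)
        k2y = ax * (rho - az) - ay
        k2z = ax * ay - beta * az
        bx, by, bz = x + 0.5 * h * k2x, y + 0.5 * h * k2y, z + 0.5 * h * k2z
        k3x = sigma * (by - bx)
        k3y = bx * (rho - bz) - by
        k3z = bx * by - beta * bz
        cx, cy, cz = x + h * k3x, y + h * k3y, z + h * k3z
        k4x = sigma * (cy - cx)
        k4y = cx * (rho - cz) - cy
        k4z = cx * cy - beta * cz
        x += (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        y += (h / 6.0) * (k1y + 2 * k2y + 2 * k3y + k4y)
        z += (h / 6.0) * (k1z + 2 * k2z + 2 * k3z + k4z)
        out[k, 0] = x
        out[k, 1] = y
        out[k, 2] = z
    return out


LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0
# One second of task time advances the Lorenz system by 0.2 dimensionless
# units (i.e. one dimensionless unit lasts 5 s).  Under the inverse reading
# the signal is an order of magnitude faster than the encoded reservoir
# leak and the generation task is unlearnable even at the rate level.
LORENZ_TIME_UNIT = 5.0
LORENZ_SCALE = 0.1


def lorenz_field(state: np.ndarray) -> np.ndarray:
    """Unscaled Lorenz vector field (dimensionless time)."""
    x, y, z = state
    return np.array(
        [
            LORENZ_SIGMA * (y - x),
            x * (LORENZ_RHO - z) - y,
            x * y - LORENZ_BETA * z,
        ]
    )


def lorenz_teacher(
    duration: float,
    dt: float,
    x0=(0.1, 0.1, 0.1),
    transient: float = 10.0,
) -> TaskSignalBundle:
    """Lorenz trajectory as a 3-channel target.

    Standard parameters sigma=10, rho=28, beta=8/3; one second of task
    time corresponds to 0.2 dimensionless units, and the dynamical
    variables are scaled by 0.1.  A transient of ``transient``
    dimensionless units is discarded.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    h = dt / LORENZ_TIME_UNIT
    n_trans = int(round(transient / h))
    n_steps = int(round(duration / dt))
    raw = _lorenz_rk4(
        n_trans + n_steps, h, x0[0], x0[1], x0[2],
        LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA,
    )
    t = np.arange(n_steps) * dt
    return TaskSignalBundle(
        t=t,
        inputs=None,
        targets=LORENZ_SCALE * raw[n_trans:],
        name="lorenz",
        params={"sigma": LORENZ_SIGMA, "rho": LORENZ_RHO, "beta": LORENZ_BETA},
    )


# ---------------------------------------------------------------------------
# delayed reaction / time-interval estimation


def _gaussian(t, center, sd, integral):
    amp = integral / (sd * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((t - center) / sd) ** 2)


def delayed_reaction_trials(
    Tt: float,
    delay: float,
    rng: np.random.Generator,
    dt: float = 1e-3,
    refractory: float = 100.0,
    gap_mean: float = 10.0,
    settle: float = 5.0,
) -> TaskSignalBundle:
    """Gaussian-pulse trials with a delayed Gaussian response target.

    Inputs are bell curves of width 0.2 s and integral 10 s; the target is
    a bell of width 1 s and integral 1 s, centered ``delay`` seconds after
    each input.  Trial onsets are separated by a 100 s refractory period
    plus an exponential gap of mean 10 s; the first onset follows an
    initial settle-in period.
    """
    onsets = []
    t0 = settle + rng.exponential(gap_mean)
    while t0 + delay + 4.0 < Tt:
        onsets.append(t0)
        t0 = t0 + refractory + rng.exponential(gap_mean)
    if not onsets:
        raise ValueError(f"Tt={Tt}s too short for a single trial at delay {delay}s")
    t = np.arange(int(round(Tt / dt))) * dt
    inp = np.zeros_like(t)
    tgt = np.zeros_like(t)
    for c in onsets:
        inp += _gaussian(t, c, 0.2, 10.0)
        tgt += _gaussian(t, c + delay, 1.0, 1.0)
    return TaskSignalBundle(
        t=t,
        inputs=inp[:, None],
        targets=tgt,
        name="delayed_reaction",
        params={"delay": delay, "onsets": onsets},
    )


# ---------------------------------------------------------------------------
# instruction switching


def _double_exp_filter(white: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """White noise convolved twice with an exponential kernel exp(-t/tau)."""
    decay = np.exp(-dt / tau)
    y1 = np.empty_like(white)
    acc = 0.0
    for k in range(len(white)):
        acc = acc * decay + white[k]
        y1[k] = acc
    y2 = np.empty_like(white)
    acc = 0.0
    for k in range(len(white)):
        acc = acc * decay + y1[k]
        y2[k] = acc
    return y2


def instruction_task_signals(
    duration: float,
    mode: str,
    rng: np.random.Generator,
    dt: float = 0.01,
    pulse_tau: float = 1.0,
) -> TaskSignalBundle:
    """Signals for the persistent instruction-switching computation task.

    Inputs (4 channels): two continuous operands (white noise filtered
    twice with an exponential kernel, time scale 1 s during training and
    10 s during testing, normalized to mean 0 / sd 0.5) and two pulsed
    instruction channels (Poisson pulses of unit height convolved with a
    1 s exponential kernel; pulse rate 0.04/s in training, 0.01/s in
    testing; overlapping pulses are shifted minimally in time so the
    summed pulse signal never exceeds 1.01).

    Targets (2 channels): the memory target ``F_m`` is +1 after a pulse on
    channel 1 and -1 after a pulse on channel 2, ramping with the integral
    of the incoming pulse during switches; the computation target is
    ``F_c = |f1 - f2| (F_m + 1)/2 - (f1 + f2)(F_m - 1)/2``, i.e. the
    absolute difference of the operands in the +1 state and their sum in
    the -1 state.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    tau_c = 1.0 if mode == "train" else 10.0
    rate = 0.04 if mode == "train" else 0.01

    cont = np.empty((n, 2))
    for k in range(2):
        y = _double_exp_filter(rng.standard_normal(n), tau_c, dt)
        y = y - y.mean()
        sd = y.std()
        cont[:, k] = 0.5 * y / sd if sd > 0 else 0.0

    # Poisson instruction pulses on two channels, merged in time and
    # shifted so the combined residual at each onset is at most 0.01.
    events = []
    for ch in (0, 1):
        tp = rng.exponential(1.0 / rate)
        while tp < duration:
            events.append((tp, ch))
            tp += rng.exponential(1.0 / rate)
    events.sort()
    shifted = []
    prev_t = -np.inf
    residual_amp = 0.0  # combined pulse amplitude left from earlier pulses
    for tp, ch in events:
        res = residual_amp * np.exp(-(tp - prev_t) / pulse_tau) if shifted else 0.0
        if res > 0.01:
            tp = prev_t + pulse_tau * np.log(residual_amp / 0.01)
            res = 0.01
        shifted.append((tp, ch))
        residual_amp = res + 1.0
        prev_t = tp
    pulses = np.zeros((n, 2))
    for tp, ch in shifted:
        mask = t >= tp
        pulses[mask, ch] += np.exp(-(t[mask] - tp) / pulse_tau)

    F_m = np.full(n, -1.0)
    level = -1.0
    bounds = [tp for tp, _ in shifted] + [np.inf]
    for (tp, ch), t_next in zip(shifted, bounds[1:]):
        sign = 1.0 if ch == 0 else -1.0
        seg = (t >= tp) & (t < t_next)
        ramp = level + sign * 2.0 * (1.0 - np.exp(-(t[seg] - tp) / pulse_tau))
        F_m[seg] = np.clip(ramp, -1.0, 1.0)
        level = F_m[seg][-1] if seg.any() else level
    f1, f2 = cont[:, 0], cont[:, 1]
    F_c = np.abs(f1 - f2) * (F_m + 1.0) / 2.0 - (f1 + f2) * (F_m - 1.0) / 2.0

    total_pulse = pulses.sum(axis=1)
    assert total_pulse.max(initial=0.0) <= 1.01 + 1e-9, "pulse overlap rule violated"
    return TaskSignalBundle(
        t=t,
        inputs=np.column_stack([cont, pulses]),
        targets=np.column_stack([F_m, F_c]),
        name=f"instruction_{mode}",
        params={"rate": rate, "tau_c": tau_c, "pulses": shifted},
    )


# ---------------------------------------------------------------------------
# stochastic pendulum plant


OMEGA0_SQ = 10.0  # squared small-amplitude angular frequency, 1/s^2
C_OMEGA0 = 0.1  # damping rate c*omega_0, 1/s


@dataclass
class PendulumState:
    phi: float
    omega: float

    @property
    def x(self) -> float:
        return float(np.sin(self.phi))

    @property
    def y(self) -> float:
        return float(-np.cos(self.phi))


def pendulum_step(
    state: PendulumState, u: float, xi: float, dt: float
) -> PendulumState:
    """Euler-Maruyama step of the damped driven pendulum.

    ``phi'' + c w0 phi' + w0^2 sin(phi) = xi + u`` with ``xi`` the white
    noise force *value* on this step (for noise intensity q the caller
    draws ``xi = sqrt(q / dt) * randn``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dom = -OMEGA0_SQ * np.sin(state.phi) - C_OMEGA0 * state.omega + xi + u
    return PendulumState(
        phi=state.phi + dt * state.omega, omega=state.omega + dt * dom
    )


def simulate_pendulum(
    duration: float,
    dt: float,
    rng: Optional[np.random.Generator] = None,
    q: float = 1.0,
    u: Optional[np.ndarray] = None,
    state: Optional[PendulumState] = None,
):
    """Simulate the pendulum; returns ``(t, phi, omega, xi)`` arrays.

    ``q`` is the white-noise intensity (<xi xi'> = q delta, q in 1/s^3);
    pass ``q=0`` for the deterministic plant.  ``u`` may tabulate a control
    force per step.
    """
    n = int(round(duration / dt))
    if state is None:
        state = PendulumState(0.0, 0.0)
    xi = (
        np.sqrt(q / dt) * rng.standard_normal(n)
        if (q > 0 and rng is not None)
        else np.zeros(n)
    )
    phi = np.empty(n)
    omega = np.empty(n)
    for k in range(n):
        uk = float(u[k]) if u is not None else 0.0
        state = pendulum_step(state, uk, xi[k], dt)
        phi[k] = state.phi
        omega[k] = state.omega
    t = (np.arange(n) + 1) * dt
    return t, phi, omega, xi
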