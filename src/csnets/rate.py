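"""Direct integration of the continuous dynamics the spiking networks encode.

These rate-level integrations serve as ground truth when testing that the
spiking simulators track the encoded system, and supply the sufficient
condition for the echo state property (``||A|| < min(lambda_V, lambda_x)``
with ``||A||`` the largest singular value).
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .topology import NeuronParams

__all__ = [
    "integrate_rate_saturating",
    "integrate_rate_dendritic",
    "echo_state_sufficient",
]


def _rk4(field: Callable, x0: np.ndarray, duration: float, dt: float):
    n_steps = int(round(duration / dt))
    x = np.array(x0, dtype=float)
    out = np.empty((n_steps + 1, x.size))
    out[0] = x
    t = 0.0
    for k in range(n_steps):
        k1 = field(t, x)
        k2 = field(t + dt / 2, x + dt / 2 * k1)
        k3 = field(t + dt / 2, x + dt / 2 * k2)
        k4 = field(t + dt, x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"rate integration diverged at t={t:.4f}s")
        t += dt
        out[k + 1] = x
    times = np.arange(n_steps + 1) * dt
    return times, out


def _input_at(input_fn, t, dim):
    if input_fn is None:
        return 0.0
    return input_fn(t)


def integrate_rate_saturating(
    A: np.ndarray,
    params: NeuronParams,
    input_fn: Optional[Callable[[float], np.ndarray]],
    x0: np.ndarray,
    duration: float,
    dt: float,
):
    """Rate dynamics directly encoded by the saturating-synapse CSN.

    Integrates, with classical RK4::

        dx/dt = -lambda_V [x]_- - lambda_x [x]_+
                + A tanh((gamma/theta) [x]_+) + I_e(t)

    with rectifications ``[x]_+ = max(x, 0)`` and ``[x]_- = min(x, 0)``.
    The general rectified form is kept even when ``lambda_x == lambda_V``
    (where the two leak terms merge into a plain ``-lambda_V x``).
    """
    A = np.asarray(A, dtype=float)
    scale = params.gamma / params.theta

    def field(t, x):
        xp = np.maximum(x, 0.0)
        xm = np.minimum(x, 0.0)
        return (
            -params.lambda_V * xm
            - params.lambda_x * xp
            + A @ np.tanh(scale * xp)
            + _input_at(input_fn, t, x.size)
        )

    return _rk4(field, x0, duration, dt)


def integrate_rate_dendritic(
    A: np.ndarray,
    lambda_x: float,
    input_fn: Optional[Callable[[float], np.ndarray]],
    x0: np.ndarray,
    duration: float,
    dt: float,
):
    """J-dimensional rate dynamics encoded by the dendritic CSN.

    Integrates ``dx/dt = -lambda_x x + A tanh(x) + c(t)`` with RK4;
    ``input_fn`` supplies ``c(t)``.
    """
    A = np.asarray(A, dtype=float)

    def field(t, x):
        return -lambda_x * x + A @ np.tanh(x) + _input_at(input_fn, t, x.size)

    return _rk4(field, x0, duration, dt)


def echo_state_sufficient(A: np.ndarray, lambda_V: float, lambda_x: float) -> bool:
    """Sufficient condition for the encoded dynamics to be enslaveable.

    True when the largest singular value of ``A`` is below
    ``min(lambda_V, lambda_x)``; the network state is then a fading-memory
    function of the recent input/feedback history.  The condition is
    sufficient, not necessary — useful reservoirs often violate it.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    norm = np.linalg.svd(A, compute_uv=False)[0]
    return bool(norm < min(lambda_V, lambda_x))
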