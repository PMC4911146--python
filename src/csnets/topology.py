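"""Network parameters, random topologies and the optimal dendritic coupling set.

A continuous-signal-coding spiking network (CSN) is a network of N leaky
integrate-and-fire neurons whose membrane potentials ``V`` and normalized
synaptic currents ``r`` jointly encode a continuous dynamical signal.  Two
variants exist:

* **saturating synapses** — each neuron encodes one continuous variable
  ``x_n = V_n + theta * r_n``; recurrent input passes through a synaptic
  tanh saturation.
* **nonlinear dendrites** — the population encodes ``J <= N`` variables
  ``x ~= Gamma @ r`` through a J x N decoding matrix ``Gamma``; each neuron
  combines slow linear, fast linear and slow nonlinear (dendritic tanh)
  input pathways whose coupling matrices are all derived from ``Gamma`` and
  a J x J slow coupling matrix ``A``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkSpec",
    "build_sparse_coupling",
    "build_decoding_matrix",
    "derive_dendritic_params",
    "draw_io_weights",
    "make_saturating_network",
    "make_dendritic_network",
]


@dataclass(frozen=True)
class NeuronParams:
    """Single-neuron and synapse constants shared by all neurons.

    Rates are in 1/s, times in s; voltages and thresholds are dimensionless.

    lambda_V : membrane leak rate.
    lambda_s : synaptic decay rate (``tau_s = 1/lambda_s``).
    lambda_x : leak rate of the encoded continuous signal.  In the
        saturating variant it is tied to the recovery current,
        ``lambda_x = lambda_s * (1 - V_r / theta)``.
    theta : spike threshold scale.  A saturating neuron spikes at
        ``theta/2`` and resets ``theta`` below; dendritic thresholds are
        derived per neuron from the fast coupling matrix.
    V_r : integrated size of the slow recovery current
        (afterdepolarization), saturating variant only.
    gamma : synaptic saturation scale (saturating variant); defaults to
        ``theta``.
    mu : spike-cost regularizer of the dendritic variant (adds
        ``mu * I`` to the fast couplings).
    sigma_eta : white-noise amplitude on the membrane equation (1/sqrt(s)).
    dt : integration step.
    """

    lambda_V: float
    lambda_s: float
    lambda_x: float
    theta: float
    V_r: float = 0.0
    gamma: Optional[float] = None
    mu: float = 0.0
    sigma_eta: float = 0.0
    dt: float = 1e-3

    def __post_init__(self):
        if self.lambda_s <= 0 or self.lambda_V <= 0:
            raise ValueError("leak rates must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.lambda_x <= self.lambda_s):
            raise ValueError("need 0 < lambda_x <= lambda_s")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.gamma is None:
            object.__setattr__(self, "gamma", self.theta)

    @property
    def a(self) -> float:
        """Slow-coupling coefficient ``a = lambda_s - lambda_x``."""
        return self.lambda_s - self.lambda_x

    @classmethod
    def saturating(
        cls,
        lambda_V: float,
        lambda_s: float,
        theta: float,
        V_r: float,
        gamma: Optional[float] = None,
        sigma_eta: float = 0.0,
        dt: float = 1e-3,
    ) -> "NeuronParams":
        """Parameters for the saturating-synapse variant.

        ``lambda_x`` follows identically from the recovery current:
        ``lambda_x = lambda_s * (1 - V_r / theta)``.
        """
        lambda_x = lambda_s * (1.0 - V_r / theta)
        return cls(
            lambda_V=lambda_V,
            lambda_s=lambda_s,
            lambda_x=lambda_x,
            theta=theta,
            V_r=V_r,
            gamma=gamma,
            sigma_eta=sigma_eta,
            dt=dt,
        )

    @classmethod
    def dendritic(
        cls,
        lambda_V: float,
        lambda_s: float,
        lambda_x: float,
        mu: float = 0.0,
        sigma_eta: float = 0.0,
        dt: float = 1e-3,
    ) -> "NeuronParams":
        """Parameters for the nonlinear-dendrite variant.

        ``theta`` is a placeholder here; dendritic thresholds are the
        per-neuron ``U_nn / 2`` stored on the :class:`NetworkSpec`.
        """
        return cls(
            lambda_V=lambda_V,
            lambda_s=lambda_s,
            lambda_x=lambda_x,
            theta=1.0,
            mu=mu,
            sigma_eta=sigma_eta,
            dt=dt,
        )


@dataclass
class NetworkSpec:
    """Static coupling structure of one CSN.

    For the saturating variant only ``A`` (N x N) is used and ``J == N``.
    For the dendritic variant ``A`` is J x J and the somatic couplings
    ``D`` (dendrite-to-soma, N x J), ``W`` (axon-to-dendrite, shared J x N,
    equal to ``Gamma``), ``U_tilde`` (slow somatic, N x N) and ``U`` (fast
    somatic, N x N) are derived from ``Gamma`` and ``A``; per-neuron
    thresholds are ``theta_vec = diag(U) / 2``.
    """

    variant: str  # "saturating" | "dendritic"
    N: int
    J: int
    A: np.ndarray
    Gamma: Optional[np.ndarray] = None
    D: Optional[np.ndarray] = None
    W: Optional[np.ndarray] = None
    U_tilde: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    theta_vec: Optional[np.ndarray] = None
    bias_b: Optional[np.ndarray] = None
    g: float = 1.5
    p: float = 0.1
    gamma_s: Optional[float] = None
    w_in: Optional[np.ndarray] = None
    w_fb: Optional[np.ndarray] = None
    reset_mode: str = "derived"  # "derived" | "always_minus_theta"

    def __post_init__(self):
        if self.variant not in ("saturating", "dendritic"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.reset_mode not in ("derived", "always_minus_theta"):
            raise ValueError(f"unknown reset_mode {self.reset_mode!r}")
        if self.variant == "saturating" and self.J != self.N:
            raise ValueError("saturating variant requires J == N")

    @property
    def n_dendrites(self) -> int:
        """Dimension over which readouts/inputs act (N or J)."""
        return self.N if self.variant == "saturating" else self.J

    def copy(self) -> "NetworkSpec":
        out = replace(self)
        for name in ("A", "D"):
            arr = getattr(out, name)
            if arr is not None:
                setattr(out, name, arr.copy())
        return out


def build_sparse_coupling(
    dim: int,
    p: float,
    g: float,
    rng: np.random.Generator,
    allow_autapses: bool = True,
) -> np.ndarray:
    """Sparse Gaussian coupling matrix with spectral radius ~= ``g``.

    Entries are zero with probability ``1 - p`` and otherwise drawn from a
    Gaussian with mean zero and variance ``g**2 / (p * dim)``, which places
    the spectral radius approximately at ``g`` for large ``dim``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if not np.isfinite(g) or g < 0:
        raise ValueError("g must be finite and non-negative")
    if p * dim * dim < 1:
        warnings.warn("expected number of connections below 1", stacklevel=2)
    mask = rng.random((dim, dim)) < p
    A = np.zeros((dim, dim))
    sd = g / np.sqrt(p * dim)
    A[mask] = rng.normal(0.0, sd, size=int(mask.sum()))
    if not allow_autapses:
        np.fill_diagonal(A, 0.0)
    return A


def build_decoding_matrix(
    J: int, N: int, gamma_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Random decoding matrix with equal column norms.

    Entries start standard normal; each column is then rescaled to
    Euclidean norm ``gamma_s``.  Equal column norms give all neurons
    identical thresholds (``theta_n = (gamma_s**2 + mu) / 2``) and a
    uniform distribution of spiking over the population; ``gamma_s`` sets
    the decoded-signal quantum contributed per spike and thereby trades
    population spike rate against coding precision.
    """
    if J < 1 or N < 1:
        raise ValueError("J and N must be >= 1")
    if gamma_s <= 0:
        raise ValueError("gamma_s must be positive")
    Gamma = rng.standard_normal((J, N))
    norms = np.linalg.norm(Gamma, axis=0)
    # a zero column has probability zero; guard anyway
    norms[norms == 0] = 1.0
    return Gamma * (gamma_s / norms)


def derive_dendritic_params(
    Gamma: np.ndarray, A: np.ndarray, params: NeuronParams
):
    """Optimal coupling set of the dendritic variant.

    Returns ``(D, W, U_tilde, U, theta_vec)`` with::

        D       = Gamma.T @ A                      (N x J)
        W       = Gamma                            (J x N, shared rows)
        U_tilde = a * Gamma.T @ Gamma + mu * lambda_s * I
        U       = Gamma.T @ Gamma + mu * I
        theta_vec[n] = U[n, n] / 2

    where ``a = lambda_s - lambda_x``.  These interrelations make the
    spiking network encode the J-dimensional continuous rate dynamics.
    """
    Gamma = np.asarray(Gamma, dtype=float)
    A = np.asarray(A, dtype=float)
    J, N = Gamma.shape
    if A.shape != (J, J):
        raise ValueError(f"A must be {J}x{J}, got {A.shape}")
    GtG = Gamma.T @ Gamma
    D = Gamma.T @ A
    U_tilde = params.a * GtG + params.mu * params.lambda_s * np.eye(N)
    U = GtG + params.mu * np.eye(N)
    theta_vec = np.diag(U) / 2.0
    return D, Gamma, U_tilde, U, theta_vec


def draw_io_weights(
    rows: int, cols: int, w_tilde: float, rng: np.random.Generator
) -> np.ndarray:
    """Input/feedback weights, i.i.d. uniform on [-w_tilde, +w_tilde]."""
    if w_tilde < 0:
        raise ValueError("w_tilde must be non-negative")
    return rng.uniform(-w_tilde, w_tilde, size=(rows, cols))


def make_saturating_network(
    N: int,
    params: NeuronParams,
    rng: np.random.Generator,
    g: float = 1.5,
    p: float = 0.1,
    allow_autapses: bool = True,
) -> NetworkSpec:
    """Assemble a saturating-synapse CSN with a random sparse coupling."""
    A = build_sparse_coupling(N, p, g, rng, allow_autapses=allow_autapses)
    return NetworkSpec(variant="saturating", N=N, J=N, A=A, g=g, p=p)


def make_dendritic_network(
    N: int,
    J: int,
    params: NeuronParams,
    rng: np.random.Generator,
    g: float = 1.5,
    p: float = 0.1,
    gamma_s: float = 0.03,
    bias_sd: float = 0.0,
    reset_mode: str = "derived",
) -> NetworkSpec:
    """Assemble a nonlinear-dendrite CSN with derived somatic couplings."""
    A = build_sparse_coupling(J, p, g, rng)
    Gamma = build_decoding_matrix(J, N, gamma_s, rng)
    D, W, U_tilde, U, theta_vec = derive_dendritic_params(Gamma, A, params)
    bias_b = rng.normal(0.0, bias_sd, size=J) if bias_sd > 0 else None
    return NetworkSpec(
        variant="dendritic",
        N=N,
        J=J,
        A=A,
        Gamma=Gamma,
        D=D,
        W=W,
        U_tilde=U_tilde,
        U=U,
        theta_vec=theta_vec,
        bias_b=bias_b,
        g=g,
        p=p,
        gamma_s=gamma_s,
        reset_mode=reset_mode,
    )
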