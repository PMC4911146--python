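"""Named experiment presets and global defaults.

Each preset fixes every static parameter of one benchmark: network variant
and size, learning-rate parameter alpha, integration step, training
duration, time constants, thresholds/recovery (saturating) or gamma_s /
mu / lambda_x (dendritic), plus per-task input/feedback amplitudes.
Global defaults used unless a preset overrides them: spectral radius
g = 1.5/s, connection probability p = 0.1, input and feedback amplitudes
w~ = 1/s, weight-update interval 0.01 s, synaptic saturation gamma equal
to the threshold theta, and no membrane noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .learning import ReadoutLearner
from .topology import (
    NeuronParams,
    make_dendritic_network,
    make_saturating_network,
)

__all__ = ["Preset", "PRESETS", "defaults", "get_preset", "build_network", "rng_streams"]


def defaults() -> dict:
    """Global simulation defaults (presets override per task)."""
    return {
        "g": 1.5,
        "p": 0.1,
        "w_tilde_f": 1.0,
        "w_tilde_i": 1.0,
        "delta_t_update": 0.01,
        "sigma_eta": 0.0,
        "gamma": "theta",  # synaptic saturation scale tied to the threshold
    }


@dataclass(frozen=True)
class Preset:
    """All static parameters of one figure-level experiment."""

    name: str
    variant: str
    task: str
    N: int
    J: int
    alpha: float
    dt: float
    T_t: float
    tau_s: float
    tau_V: float
    # saturating-variant fields
    theta: float = 0.03
    V_r_factor: float = 0.0  # V_r = V_r_factor * theta
    # dendritic-variant fields
    gamma_s: float = 0.03
    mu: float = 0.0
    lambda_x: float = 1.0
    bias_sd: float = 0.0
    # shared
    g: float = 1.5
    p: float = 0.1
    w_tilde_i: float = 1.0
    w_tilde_f: float = 1.0
    sigma_eta: float = 0.0
    scheme: str = "rk4"
    mode: str = "recurrent"
    mix: float = 1.0
    allow_autapses: bool = True
    K_out: int = 1
    delta_t_update: float = 0.01
    extras: dict = field(default_factory=dict)


PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        Preset(
            name="fig3b", variant="dendritic", task="sine",
            N=500, J=50, alpha=0.1, gamma_s=0.03, dt=1e-3, T_t=100.0,
            mu=0.0, tau_s=0.1, tau_V=0.1, lambda_x=1.0,
        ),
        Preset(
            name="fig3d", variant="saturating", task="sawtooth",
            N=50, J=50, alpha=0.1, dt=1e-4, T_t=100.0,
            tau_s=0.1, tau_V=0.1, V_r_factor=0.9, theta=0.03,
            scheme="euler",
        ),
        Preset(
            name="fig3e_sat", variant="saturating", task="camel",
            N=50, J=50, alpha=0.1, dt=1e-3, T_t=100.0,
            tau_s=0.1, tau_V=0.1, V_r_factor=0.9, theta=0.03,
        ),
        Preset(
            name="fig3e_dendr", variant="dendritic", task="camel",
            N=500, J=50, alpha=0.1, gamma_s=0.03, dt=1e-3, T_t=100.0,
            mu=0.0, tau_s=0.1, tau_V=0.1, lambda_x=1.0,
        ),
        Preset(
            name="fig3fgh", variant="dendritic", task="lorenz",
            N=1600, J=800, alpha=0.1, gamma_s=0.03, dt=1e-3, T_t=200.0,
            mu=0.0, tau_s=0.1, tau_V=0.1, lambda_x=1.0, K_out=3,
        ),
        Preset(
            name="fig4abc", variant="saturating", task="delayed_reaction",
            N=200, J=200, alpha=0.1, dt=1e-3, T_t=800.0,
            tau_s=0.1, tau_V=0.05, V_r_factor=0.54, theta=0.1,
            sigma_eta=0.001, allow_autapses=False, mode="readout",
            scheme="euler",
        ),
        Preset(
            name="fig4d", variant="dendritic", task="switching",
            N=300, J=300, alpha=50.0, gamma_s=0.5, dt=1e-2, T_t=1000.0,
            mu=0.0, tau_s=1.0, tau_V=0.5, lambda_x=0.02,
            g=75.0, K_out=2, w_tilde_f=250.0,
            extras={
                "w_tilde_i_cont": 250.0,
                "w_tilde_i_pulse": 100.0,
                "const_input_range": (0.0, 250.0),
            },
        ),
        Preset(
            name="fig5", variant="dendritic", task="pendulum",
            N=500, J=300, alpha=0.1, gamma_s=0.03, dt=1e-3, T_t=1000.0,
            mu=20.0 / 500**2, tau_s=0.1, tau_V=0.05, lambda_x=10.0,
            bias_sd=0.01, K_out=3, w_tilde_i=27.0, mode="feedback",
            mix=0.9, scheme="euler",
            extras={"w_tilde_f_xy": 100.0, "w_tilde_f_omega": 20.0},
        ),
    ]
}


def get_preset(name: str, **overrides) -> Preset:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    preset = PRESETS[name]
    if overrides:
        extras = {**preset.extras, **overrides.pop("extras", {})}
        if preset.variant == "dendritic" and "N" in overrides and "mu" not in overrides:
            # the spike-cost regularizer scales with network size
            if preset.mu > 0:
                overrides["mu"] = preset.mu * preset.N**2 / overrides["N"] ** 2
        preset = replace(preset, extras=extras, **overrides)
    return preset


def rng_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Independent, reproducible substreams derived from one run seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def make_params(preset: Preset) -> NeuronParams:
    lam_s = 1.0 / preset.tau_s
    lam_V = 1.0 / preset.tau_V
    if preset.variant == "saturating":
        return NeuronParams.saturating(
            lambda_V=lam_V, lambda_s=lam_s, theta=preset.theta,
            V_r=preset.V_r_factor * preset.theta,
            sigma_eta=preset.sigma_eta, dt=preset.dt,
        )
    return NeuronParams.dendritic(
        lambda_V=lam_V, lambda_s=lam_s, lambda_x=preset.lambda_x,
        mu=preset.mu, sigma_eta=preset.sigma_eta, dt=preset.dt,
    )


def build_network(preset: Preset, rng: np.random.Generator):
    """Instantiate (spec, params, learner) for a preset.

    Input/feedback weights are task specific and drawn by the experiment
    drivers; the learner covers ``K_out`` outputs with N (saturating) or J
    (dendritic) regressors.
    """
    params = make_params(preset)
    if preset.variant == "saturating":
        spec = make_saturating_network(
            preset.N, params, rng, g=preset.g, p=preset.p,
            allow_autapses=preset.allow_autapses,
        )
    else:
        spec = make_dendritic_network(
            preset.N, preset.J, params, rng, g=preset.g, p=preset.p,
            gamma_s=preset.gamma_s, bias_sd=preset.bias_sd,
        )
    learner = ReadoutLearner.init(
        preset.K_out, spec.n_dendrites, preset.alpha, preset.delta_t_update
    )
    return spec, params, learner
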