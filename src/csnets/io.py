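"""Serialization and reproducible experiment runs on disk.

Network matrices go into a ``.npz`` array container; everything scalar
lives in JSON manifests.  ``run_preset`` executes a named experiment
end-to-end and writes a manifest, a metrics summary, the spike event list
(plain text: time_s neuron_id) and the output channel table into a run
directory.  Runs are bit-reproducible: the same preset and seed produce
byte-identical metrics summaries.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import experiments
from .presets import get_preset
from .topology import NetworkSpec

__all__ = ["save_network", "load_network", "run_preset"]

_ARRAY_FIELDS = (
    "A", "Gamma", "D", "W", "U_tilde", "U", "theta_vec", "bias_b", "w_in", "w_fb"
)


def save_network(spec: NetworkSpec, path) -> None:
    """Write a NetworkSpec as <path>.npz plus <path>.json metadata."""
    path = Path(path)
    arrays = {f: getattr(spec, f) for f in _ARRAY_FIELDS if getattr(spec, f) is not None}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "variant": spec.variant,
        "N": spec.N,
        "J": spec.J,
        "g": spec.g,
        "p": spec.p,
        "gamma_s": spec.gamma_s,
        "reset_mode": spec.reset_mode,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_network(path) -> NetworkSpec:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = dict(np.load(path.with_suffix(".npz")))
    return NetworkSpec(**meta, **arrays)


_SCALAR_TYPES = (int, float, str, bool, type(None))


def _scalar_metrics(result: dict) -> dict:
    return {
        k: v
        for k, v in result.items()
        if isinstance(v, _SCALAR_TYPES) or isinstance(v, (np.floating, np.integer))
    }


def run_preset(
    preset_name: str,
    seed: int,
    out_dir,
    overrides: Optional[dict] = None,
) -> dict:
    """Run one named experiment and persist its outputs.

    Writes ``manifest.json`` (resolved parameters and seed),
    ``metrics.json`` (scalar results), ``spikes.txt`` and ``outputs.txt``
    under ``out_dir``.  Returns the scalar metrics.
    """
    from .presets import Preset

    overrides = dict(overrides or {})
    preset_fields = set(Preset.__dataclass_fields__)
    preset_overrides = {k: v for k, v in overrides.items() if k in preset_fields}
    preset = get_preset(preset_name, **preset_overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset.task in ("sine", "sawtooth", "camel"):
        result = experiments.run_pattern_experiment(preset_name, seed, **overrides)
    elif preset.task == "lorenz":
        result = experiments.run_lorenz_experiment(seed, preset_name, **overrides)
    elif preset.task == "switching":
        result = experiments.run_switching_experiment(seed, **overrides)
    elif preset.task == "delayed_reaction":
        result = experiments.run_delayed_reaction_experiment(seed, **overrides)
    elif preset.task == "pendulum":
        model = experiments.train_pendulum_world_model(seed, **preset_overrides)
        result = experiments.run_pendulum_control(seed, model=model)
    else:
        raise ValueError(f"preset task {preset.task!r} has no runner")
    manifest = {
        "preset": dataclasses.asdict(preset),
        "seed": seed,
        "overrides": {k: repr(v) for k, v in overrides.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    metrics = _scalar_metrics(result)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    if "spike_log" in result and np.size(result["spike_log"]):
        np.savetxt(
            out / "spikes.txt", result["spike_log"], fmt="%.6f %d",
            header="time_s neuron_id",
        )
    if "times" in result and "z" in result:
        np.savetxt(
            out / "outputs.txt",
            np.column_stack([result["times"], np.atleast_2d(result["z"].T).T]),
            header="time_s " + " ".join(f"z_{k}" for k in range(result["z"].shape[1])),
        )
    return metrics
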