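"""Quantitative diagnostics for trained networks.

Covers mean per-neuron spike rates, a phase-aligned recall error for
periodic patterns (pattern recall accumulates a harmless phase shift from
tiny period mismatches, so the error is minimized over circular time
shifts), the normalized delayed-reaction error with the extinguished
network as the unit baseline, and the Lorenz tent-map diagnostic relating
successive maxima of the z-coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

__all__ = [
    "mean_spike_rate",
    "phase_aligned_nrmse",
    "delayed_reaction_error",
    "tent_map",
    "TentMapSample",
]


def mean_spike_rate(
    spike_log: np.ndarray, N: int, duration: float, washout: float = 1.0
) -> float:
    """Population-mean firing rate in Hz over (washout, duration].

    ``spike_log`` holds (time_s, neuron_id) rows with times relative to
    the start of the measured run.
    """
    if duration <= washout:
        raise ValueError("duration must exceed washout")
    spike_log = np.asarray(spike_log)
    if spike_log.size == 0:
        return 0.0
    t = spike_log[:, 0]
    count = int(np.count_nonzero((t > washout) & (t <= duration)))
    return count / (N * (duration - washout))


def phase_aligned_nrmse(
    output: np.ndarray, target: np.ndarray, period_hint: Optional[float] = None
) -> float:
    """RMSE minimized over circular time shifts, in units of target sd.

    Cross-correlation via FFT finds the best shift at grid resolution.
    ``period_hint`` (in samples per period is unnecessary; shifts cover
    the full circular range) is accepted for interface symmetry.
    """
    output = np.ravel(output).astype(float)
    target = np.ravel(target).astype(float)
    if output.shape != target.shape:
        raise ValueError("signals must share the grid")
    sd = target.std()
    if sd == 0:
        raise ValueError("constant target: normalization undefined")
    n = len(target)
    # RMSE(s)^2 = mean(o^2) + mean(f^2) - 2/n * sum_k o_k f_{k-s}
    cross = np.fft.irfft(np.fft.rfft(output) * np.conj(np.fft.rfft(target)), n)
    mse = np.mean(output**2) + np.mean(target**2) - 2.0 * cross / n
    return float(np.sqrt(max(mse.min(), 0.0)) / sd)


def delayed_reaction_error(
    output: np.ndarray, target: np.ndarray, n_trials: int = 1
) -> float:
    """RMS error normalized so the extinguished (silent) network scores 1.

    Both the response error and the baseline are normalized by the number
    of test trials, so the ratio is independent of ``n_trials``; the
    argument documents the per-trial convention.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    output = np.ravel(output)
    target = np.ravel(target)
    base = np.sqrt(np.mean(target**2))
    if base == 0:
        raise ValueError("zero target: baseline undefined")
    return float(np.sqrt(np.mean((output - target) ** 2)) / base)


@dataclass
class TentMapSample:
    """Successive-maxima pairs of a Lorenz-like z series with outlier flags."""

    pairs: np.ndarray  # (n_pairs, 2): (z_{n-1}, z_n)
    outliers: np.ndarray  # bool per pair
    band_sd: float

    @property
    def fraction_within_band(self) -> float:
        if len(self.pairs) == 0:
            return float("nan")
        return 1.0 - self.outliers.mean()


def _local_maxima(z: np.ndarray, min_sep: int) -> np.ndarray:
    """Indices of strict local maxima, at least min_sep samples apart."""
    cand = np.flatnonzero((z[1:-1] > z[:-2]) & (z[1:-1] > z[2:])) + 1
    kept: list[int] = []
    for i in cand:
        if kept and i - kept[-1] < min_sep:
            if z[i] > z[kept[-1]]:
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return np.array(kept, dtype=int)


def _refined_maxima_values(z: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Parabolic interpolation of peak heights (grid-resolution independent)."""
    vals = z[idx].astype(float)
    inner = (idx > 0) & (idx < len(z) - 1)
    i = idx[inner]
    a, b, c = z[i - 1], z[i], z[i + 1]
    denom = a - 2 * b + c
    ok = denom < 0
    corr = np.zeros(len(i))
    corr[ok] = -((a - c)[ok] ** 2) / (8.0 * denom[ok])
    vals[inner] = b + corr
    return vals


@lru_cache(maxsize=8)
def _reference_tent_map(dt: float = 0.005):
    """Binned median of the ideal tent map from a long Lorenz integration.

    Built at the query's sampling resolution so that discretization bias
    in peak heights cancels between reference and sample, and from an
    off-attractor initial condition distinct from the default teacher.
    """
    from .tasks import LORENZ_TIME_UNIT, lorenz_teacher

    # 2500 dimensionless units ~ 3300 z-maxima, enough for stable bins
    ref = lorenz_teacher(duration=2500.0 * LORENZ_TIME_UNIT, dt=dt, x0=(1.3, 0.9, 12.0))
    z = ref.targets[:, 2]
    idx = _local_maxima(z, min_sep=int(round(0.5 * LORENZ_TIME_UNIT / dt)))
    zm = _refined_maxima_values(z, idx)
    pairs = np.column_stack([zm[:-1], zm[1:]])
    order = np.argsort(pairs[:, 0])
    xs, ys = pairs[order, 0], pairs[order, 1]
    edges = np.linspace(xs[0], xs[-1], 81)
    centers = 0.5 * (edges[:-1] + edges[1:])
    med = np.full(len(centers), np.nan)
    spread = np.full(len(centers), np.nan)
    for b in range(len(centers)):
        sel = (xs >= edges[b]) & (xs < edges[b + 1])
        if sel.sum() >= 3:
            med[b] = np.median(ys[sel])
            spread[b] = 1.4826 * np.median(np.abs(ys[sel] - med[b]))
    good = np.isfinite(med)
    map_x, map_y = centers[good], med[good]
    resid = ys - np.interp(xs, map_x, map_y)
    robust_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    # scatter varies strongly along the map (widest at the apex); keep a
    # per-position width, floored by the global value
    map_sd = np.maximum(spread[good], robust_sd)
    return map_x, map_y, map_sd, float(robust_sd)


def tent_map(
    z_series: np.ndarray,
    dt: float,
    band_factor: float = 3.0,
    band_floor: float = 0.05,
) -> TentMapSample:
    """Successive-maxima map of a z series against the ideal Lorenz map.

    Maxima are strict neighbor-comparison peaks separated by at least
    half a dimensionless Lorenz unit (successive z-maxima are ~0.75 units
    apart), which also rejects the fast spike-coding ripple riding on a
    generated trajectory.  Pairs farther than ``band_factor`` reference robust
    standard deviations from the ideal map (binned median of a long
    reference integration, on the 0.1-scaled z) are flagged as outliers.
    The band has an absolute floor (default 0.05, about 1% of the
    attractor extent): the diagnostic exists to count gross error loops,
    and on the legs of the map the ideal scatter is thinner than the
    encoding blur of any trained generator.
    """
    from .tasks import LORENZ_TIME_UNIT

    z_series = np.ravel(z_series)
    idx = _local_maxima(z_series, min_sep=max(1, int(round(0.5 * LORENZ_TIME_UNIT / dt))))
    if len(idx) < 2:
        raise ValueError("fewer than two local maxima in series")
    zm = _refined_maxima_values(z_series, idx)
    pairs = np.column_stack([zm[:-1], zm[1:]])
    map_x, map_y, map_sd, ref_sd = _reference_tent_map(dt)
    pred = np.interp(pairs[:, 0], map_x, map_y)
    band = np.maximum(np.interp(pairs[:, 0], map_x, map_sd), band_floor / band_factor)
    resid = pairs[:, 1] - pred
    out = np.abs(resid) > band_factor * band
    # points outside the reference support cannot be judged against the map
    margin = band_factor * ref_sd
    out |= pairs[:, 0] < map_x[0] - margin
    out |= pairs[:, 0] > map_x[-1] + margin
    return TentMapSample(pairs=pairs, outliers=out, band_sd=ref_sd)
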