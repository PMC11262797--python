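"""Poisson spike generation from firing rates.

The rate model carries no spikes; for spike-level reanalysis each neuron
emits counts per time bin from an inhomogeneous Poisson process with mean
rate*dt, and spike times are jittered uniformly within their bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TuningCurve", "SpikeTrain", "tuning_rate", "poisson_spikes"]


@dataclass(frozen=True)
class TuningCurve:
    """Gaussian place-field tuning f(z) = Ar exp(-(x_i - z)^2 / 2 a^2)."""

    x_i: float
    Ar: float
    a: float

    def __post_init__(self) -> None:
        if self.Ar <= 0 or self.a <= 0:
            raise ValueError("Ar and a must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    neuron_id: int
    spike_times: np.ndarray  # ms, sorted
    dt_bin: float
    seed: int


def tuning_rate(curve: TuningCurve, z: np.ndarray | float) -> np.ndarray | float:
    """Rate of a place cell at animal position z under its tuning curve."""
    return curve.Ar * np.exp(-((curve.x_i - np.asarray(z)) ** 2) / (2 * curve.a**2))


def poisson_spikes(
    rate: np.ndarray,
    times: np.ndarray,
    seed: int,
    neuron_id: int = 0,
    dt_bin: float | None = None,
) -> SpikeTrain:
    """Sample a spike train from a rate trace.

    Per bin of width ``dt_bin`` (default: the trace sampling step) the count
    is Poisson with mean rate*dt_bin, and each spike is placed uniformly at
    random inside its bin.  Reproducible given the seed.
    """
    rate = np.asarray(rate, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(rate < 0):
        raise ValueError("negative rates are not valid Poisson intensities")
    dt = times[1] - times[0]
    if dt_bin is None:
        dt_bin = dt
    if dt_bin < dt:
        raise ValueError("dt_bin must be at least the trace sampling step")
    stride = int(round(dt_bin / dt))
    n_bins = len(rate) // stride
    binned = rate[: n_bins * stride].reshape(n_bins, stride).mean(axis=1)
    t0 = times[0] + np.arange(n_bins) * dt_bin
    rng = np.random.default_rng(seed)
    counts = rng.poisson(binned * dt_bin)
    spikes = np.repeat(t0, counts) + rng.uniform(0, dt_bin, counts.sum())
    return SpikeTrain(neuron_id, np.sort(spikes), dt_bin, seed)
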