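"""Core network dynamics: recurrent kernel, divisive-normalization firing
rate, slow adaptation, and the Euler integrator that produces a trace.

The continuum model is

    tau   dU/dt = -U + rho * Int J(x,x') r(x') dx' - V + I_ext(x)
    r(x)        = g U(x)^2 / (1 + k rho * Int U(x')^2 dx')
    tau_v dV/dt = -V + m U

discretized on a uniform grid with spacing 1/rho (1D) or area 1/rho (2D),
so that ``rho * Int f dx`` becomes a plain sum over neurons.  This folding
keeps the dynamics invariant under grid refinement at fixed rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np

from .environments import NeuronGrid, build_linear_track
from .params import ModelParams

__all__ = [
    "NetworkState",
    "SimulationTrace",
    "build_connectivity",
    "firing_rate",
    "external_input",
    "euler_step",
    "simulate",
    "decode_center",
]


class IntegrationDivergedError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass
class NetworkState:
    """Synaptic input U, adaptation V, firing rate r at one instant (t in ms)."""

    U: np.ndarray
    V: np.ndarray
    r: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.U.copy(), self.V.copy(), self.r.copy(), self.t)


@dataclass
class SimulationTrace:
    """Strided history of a simulation run.

    ``z`` is the decoded bump center, ``s = z - input_center`` the
    displacement (ring-wrapped where applicable).  ``r_t``/``U_t``/``V_t``
    are (n_samples, n_neurons).
    """

    times: np.ndarray
    r_t: np.ndarray
    U_t: np.ndarray
    V_t: np.ndarray
    input_center: np.ndarray
    z: np.ndarray
    s: np.ndarray
    bump_height: np.ndarray
    params: ModelParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt_sample(self) -> float:
        return float(self.times[1] - self.times[0])

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("times", "r_t", "U_t", "V_t", "input_center", "z", "s",
                         "bump_height"):
                f.create_dataset(name, data=getattr(self, name))
            if self.params is not None:
                for key, val in self.params.to_dict().items():
                    f.attrs[key] = -1.0 if val is None else val
            for key, val in self.meta.items():
                f.attrs[f"meta_{key}"] = val

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTrace":
        with h5py.File(path, "r") as f:
            arrays = {
                name: f[name][()]
                for name in ("times", "r_t", "U_t", "V_t", "input_center", "z",
                             "s", "bump_height")
            }
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return cls(**arrays, meta=meta)


def build_connectivity(grid: NeuronGrid, J0: float, a: float) -> np.ndarray:
    """Gaussian recurrent kernel on the grid's metric.

    1D: J = J0/(sqrt(2 pi) a) exp(-dist^2 / 2 a^2)
    2D: J = J0/(2 pi a^2)     exp(-dist^2 / 2 a^2)

    Peak strength sits on the diagonal; entries depend only on pairwise
    distance, which on the ring makes the kernel translation invariant.
    """
    if a <= 0:
        raise ValueError("interaction range a must be positive")
    dist = grid.pairwise_distance()
    if grid.positions.ndim == 1:
        prefactor = J0 / (np.sqrt(2 * np.pi) * a)
    else:
        prefactor = J0 / (2 * np.pi * a**2)
    return prefactor * np.exp(-(dist**2) / (2 * a**2))


def firing_rate(U: np.ndarray, params: ModelParams) -> np.ndarray:
    """Divisive normalization: r = g U^2 / (1 + k rho Int U^2 dx).

    On the unit-density-folded grid the normalization integral is the plain
    sum of U^2 over neurons.  The denominator is >= 1, so r is bounded and
    identically zero input maps to zero rate.
    """
    U2 = U**2
    return params.g * U2 / (1.0 + params.k * U2.sum())


def external_input(
    grid: NeuronGrid, center: np.ndarray | float, params: ModelParams
) -> np.ndarray:
    """Gaussian location input, peak ``alpha`` at ``center``, width 2*sigma.

    I_ext(x) = alpha * exp(-dist(x, center)^2 / (4 sigma^2)); in the T-maze
    the same form applies with Euclidean distance, with the input width set
    to sigma = a/sqrt(2) (denominator 2 a^2) by the tmaze preset.
    """
    if params.alpha == 0.0:
        return np.zeros(grid.n)
    dist = grid.distance_to(center)
    return params.alpha * np.exp(-(dist**2) / (4.0 * params.sigma_eff**2))


def euler_step(
    state: NetworkState,
    params: ModelParams,
    kernel: np.ndarray,
    drive: np.ndarray | float,
    silence: bool = False,
) -> NetworkState:
    """One forward-Euler step of the coupled U/V dynamics (in place).

    ``silence=True`` clamps the firing rate to zero for this step (the
    transient-inactivation manipulation) while U and V keep integrating.
    """
    r = np.zeros_like(state.U) if silence else state.r
    recurrent = kernel @ r
    state.U += params.dt / params.tau * (-state.U + recurrent - state.V + drive)
    state.V += params.dt / params.tau_v * (-state.V + params.m * state.U)
    state.r = firing_rate(state.U, params)
    state.t += params.dt
    if not np.isfinite(state.U).all():
        raise IntegrationDivergedError(
            f"non-finite synaptic input at t = {state.t:.1f} ms"
        )
    return state


def decode_center(
    r: np.ndarray, grid: NeuronGrid, top_k: int = 10
) -> float | np.ndarray:
    """Population-vector decode of the bump center from the top_k most
    active neurons (rate-weighted circular mean on the ring, plain weighted
    mean in 2D).  Returns NaN when the network is silent.
    """
    idx = np.argsort(r)[-top_k:]
    w = r[idx]
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        return np.nan if grid.positions.ndim == 1 else np.full(2, np.nan)
    if grid.topology == "ring":
        L = grid.circumference
        ang = grid.positions[idx] * (2 * np.pi / L)
        mean = np.angle(np.sum(w * np.exp(1j * ang)))
        return (mean / (2 * np.pi) * L) % L
    return (w[:, None] * grid.positions[idx]).sum(0) / total


def _default_input_path(params: ModelParams) -> Callable[[float], float]:
    def path(t_ms: float) -> float:
        return params.v_ext_ms * t_ms

    return path


def simulate(
    params: ModelParams,
    grid: NeuronGrid | None = None,
    *,
    duration_ms: float | None = None,
    warmup_ms: float = 500.0,
    input_path: Callable[[float], np.ndarray | float] | None = None,
    silence_windows: Sequence[tuple[float, float]] = (),
    initial_state: NetworkState | None = None,
    stride: int = 5,
    store_states: bool = False,
    top_k: int = 10,
) -> SimulationTrace:
    """Integrate the network over a protocol and return the sampled trace.

    The run is deterministic: the rate model has no noise source.  Unless an
    initial state is supplied, the network is warmed up for ``warmup_ms``
    with the input frozen at its starting position so the simulation starts
    on the tracking branch rather than from the transient.

    ``silence_windows`` is a list of (start_ms, duration_ms) pairs during
    which the population rate is clamped to zero while the input continues.
    """
    if grid is None:
        grid = build_linear_track()
    if params.dt > params.tau / 5:
        import warnings

        warnings.warn(
            f"dt = {params.dt} ms is coarse for tau = {params.tau} ms; "
            "expect Euler error",
            stacklevel=2,
        )
    path = input_path or _default_input_path(params)
    T = params.T_total * 1000.0 if duration_ms is None else duration_ms
    kernel = build_connectivity(grid, params.J0, params.a)
    for w0, wd in silence_windows:
        if wd < 0 or w0 < 0 or w0 + wd > T:
            raise ValueError("silence window outside the simulated run")

    if initial_state is None:
        # Seed a stereotyped Gaussian bump at the path origin, then let the
        # warmup relax it onto the attractor (with the input frozen at its
        # starting position).  Starting from zeros instead can land in the
        # input-slaved low branch when the self-sustained bump coexists with
        # it, and gives no state at all for alpha = 0.
        d0 = grid.distance_to(path(0.0))
        state = NetworkState(
            U=1.0 * np.exp(-(d0**2) / (4 * params.a**2)),
            V=np.zeros(grid.n),
            r=np.zeros(grid.n),
            t=0.0,
        )
        drive0 = external_input(grid, path(0.0), params)
        for _ in range(int(round(warmup_ms / params.dt))):
            euler_step(state, params, kernel, drive0)
        state.t = 0.0
    else:
        state = initial_state.copy()
        state.r = firing_rate(state.U, params)

    n_steps = int(round(T / params.dt))
    sample_idx = range(0, n_steps, stride)
    n_samples = len(sample_idx)
    times = np.empty(n_samples)
    z = np.empty(n_samples) if grid.positions.ndim == 1 else np.empty((n_samples, 2))
    centers = np.empty_like(z)
    heights = np.empty(n_samples)
    shape = (n_samples, grid.n) if store_states else (0, grid.n)
    r_t = np.empty(shape)
    U_t = np.empty(shape)
    V_t = np.empty(shape)
    probe_rates = np.empty((n_samples, grid.n)) if not store_states else r_t

    j = 0
    for i in range(n_steps):
        t = i * params.dt
        silenced = any(w0 <= t < w0 + wd for w0, wd in silence_windows)
        if i % stride == 0:
            r_now = np.zeros(grid.n) if silenced else state.r
            times[j] = t
            c = path(t)
            centers[j] = c if np.ndim(c) else float(c)
            z[j] = decode_center(r_now, grid, top_k)
            heights[j] = r_now.max()
            probe_rates[j] = r_now
            if store_states:
                U_t[j] = state.U
                V_t[j] = state.V
            j += 1
        drive = external_input(grid, path(t), params)
        euler_step(state, params, kernel, drive, silence=silenced)

    if grid.topology == "ring":
        s = np.asarray(grid.wrap(z - centers))
    else:
        s = z - centers
    return SimulationTrace(
        times=times,
        r_t=probe_rates,
        U_t=U_t,
        V_t=V_t,
        input_center=centers,
        z=z,
        s=s,
        bump_height=heights,
        params=params,
        meta={"stride": stride, "warmup_ms": warmup_ms},
    )
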