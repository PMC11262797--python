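"""Decoding and phenomenology extraction from simulation traces.

Everything here works on sampled traces (`SimulationTrace` or bare arrays):
theta-cycle segmentation of the bump-input displacement s(t), per-neuron
firing-peak phase records, bimodal/unimodal classification, phase-position
probability heatmaps, rate correlograms and spectra, and per-cycle sweep
lengths.

Phase conventions.  A theta cycle starts at a positive-going crossing of
s(t) through its running mean, so phase 0 sits mid-forward-sweep: the
forward window (bump center moving ahead, s rising) spans phases
(-pi/2, pi/2] and the backward window (pi/2, 3pi/2].  Forward-peak phases
are reported in (-pi/2, pi/2] (decreasing from +pi/2 to -pi/2 across the
field traversal), backward-peak phases in (pi/2, 3pi/2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .environments import NeuronGrid
from .model import SimulationTrace, decode_center

__all__ = [
    "ThetaCycles",
    "PhaseRecord",
    "PhaseHeatmap",
    "bump_center",
    "segment_cycles",
    "phase_record",
    "classify_modality",
    "phase_position_heatmap",
    "autocorrelogram",
    "crosscorrelogram",
    "rate_spectrum",
    "sweep_lengths",
    "bump_height_by_window",
]


class NonOscillatoryTraceError(ValueError):
    """The displacement trace has no usable theta oscillation."""


@dataclass(frozen=True)
class ThetaCycles:
    """Cycle boundaries (ms) of the bump oscillation and derived periods."""

    boundaries: np.ndarray  # start times, strictly increasing
    periods: np.ndarray  # per-cycle durations (ms), len = len(boundaries) - 1

    @property
    def n(self) -> int:
        return len(self.periods)

    @property
    def mean_period(self) -> float:
        return float(self.periods.mean())

    @property
    def mean_freq(self) -> float:
        """Mean oscillation frequency in Hz."""
        return 1000.0 / self.mean_period

    def phase_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Raw phase in [0, 2 pi) and cycle index for each time (ms).

        Times outside the segmented span get cycle index -1.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        valid = (idx >= 0) & (idx < self.n)
        safe = np.clip(idx, 0, self.n - 1)
        phase = 2 * np.pi * (t - self.boundaries[safe]) / self.periods[safe]
        return np.where(valid, phase, np.nan), np.where(valid, idx, -1)


@dataclass(frozen=True)
class PhaseRecord:
    """Firing peaks of one probe neuron in one theta cycle.

    ``t_f``/``t_b`` are the forward/backward peak times (ms), ``phi_f``/
    ``phi_b`` the corresponding phases (rad), ``peak_rate_*`` the rates at
    those peaks; missing peaks are NaN.  ``x_norm`` is the normalized animal
    position in the neuron's firing field at the forward (preferentially)
    peak, in [-1, 1]; ``h`` the bump-to-neuron displacement at that moment.
    """

    cycle_index: int
    t_f: float
    t_b: float
    phi_f: float
    phi_b: float
    peak_rate_f: float
    peak_rate_b: float
    x_norm: float
    h: float


def bump_center(r: np.ndarray, grid: NeuronGrid, top_k: int = 10):
    """Decoded bump position; see :func:`thetasweep.model.decode_center`.

    A silent population (all rates zero, e.g. inside a silencing window)
    yields NaN rather than an arbitrary position.
    """
    return decode_center(np.asarray(r, dtype=float), grid, top_k)


def segment_cycles(
    s: np.ndarray,
    times: np.ndarray,
    min_amplitude: float = 0.01,
    smooth_ms: float = 5.0,
    min_period_ms: float = 50.0,
) -> ThetaCycles:
    """Segment the displacement trace into theta cycles.

    Boundaries are positive-going crossings of s(t) through its mean after
    light smoothing; crossings closer than ``min_period_ms`` to the previous
    boundary are treated as ripple and merged into the ongoing cycle.
    Raises :class:`NonOscillatoryTraceError` when the oscillation amplitude
    is below ``min_amplitude`` (meters) or fewer than two crossings exist
    (e.g. smooth tracking).
    """
    s = np.asarray(s, dtype=float)
    times = np.asarray(times, dtype=float)
    finite = np.isfinite(s)
    if not finite.all():
        if finite.sum() < 10:
            raise NonOscillatoryTraceError("displacement trace mostly undefined")
        # bridge undefined stretches (e.g. silencing windows) linearly; any
        # crossings inside a bridge are as good a boundary as the data allow
        s = np.interp(times, times[finite], s[finite])
    dt = times[1] - times[0]
    w = max(int(round(smooth_ms / dt)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        s = np.convolve(s, kernel, mode="same")
    sm = s - s.mean()
    amp = (np.percentile(sm, 97.5) - np.percentile(sm, 2.5)) / 2
    if amp < min_amplitude:
        raise NonOscillatoryTraceError(
            f"oscillation amplitude {amp:.4f} m below floor {min_amplitude} m"
        )
    up = np.nonzero((sm[:-1] < 0) & (sm[1:] >= 0))[0]
    # discard crossings inside the smoothing edge region
    up = up[(up >= w) & (up < len(sm) - w)]
    if len(up) < 2:
        raise NonOscillatoryTraceError("fewer than two mean-crossings found")
    # linear interpolation of the crossing instant
    frac = -sm[up] / (sm[up + 1] - sm[up])
    boundaries = times[up] + frac * dt
    kept = [boundaries[0]]
    for b in boundaries[1:]:
        if b - kept[-1] >= min_period_ms:
            kept.append(b)
    boundaries = np.asarray(kept)
    if len(boundaries) < 2:
        raise NonOscillatoryTraceError("fewer than two mean-crossings found")
    periods = np.diff(boundaries)
    return ThetaCycles(boundaries=boundaries, periods=periods)


def _wrap_forward(phi: np.ndarray | float) -> np.ndarray | float:
    """Map a raw phase in [0, 2 pi) into (-pi/2, 3 pi/2]."""
    return np.where(np.asarray(phi) > 1.5 * np.pi, np.asarray(phi) - 2 * np.pi, phi)


def phase_record(
    rate: np.ndarray,
    times: np.ndarray,
    cycles: ThetaCycles,
    *,
    input_center: np.ndarray | None = None,
    neuron_pos: float = 0.0,
    z: np.ndarray | None = None,
    a: float = 0.4,
    prominence_frac: float = 0.01,
) -> list[PhaseRecord]:
    """Per-cycle firing peaks and phases of one neuron's rate trace.

    Local maxima with prominence above ``prominence_frac`` of the trace
    maximum are assigned to forward/backward windows by their phase; at most
    the largest peak is kept per window per cycle.  When ``input_center``
    is given, ``x_norm`` is the normalized field position of the animal at
    the peak, and when ``z`` is given, ``h`` is the decoded bump-to-neuron
    displacement.
    """
    rate = np.asarray(rate, dtype=float)
    times = np.asarray(times, dtype=float)
    floor = prominence_frac * rate.max()
    if floor <= 0:
        return []
    peaks, _ = signal.find_peaks(rate, prominence=floor)
    phi_raw, cyc = cycles.phase_at(times[peaks])
    records: dict[int, dict[str, tuple]] = {}
    for p, phi, ci in zip(peaks, phi_raw, cyc):
        if ci < 0 or not np.isfinite(phi):
            continue
        phi_w = float(_wrap_forward(phi))
        ci = int(ci)
        if phi_w <= 0.5 * np.pi:  # forward window (-pi/2, pi/2]
            # a peak in the tail (phase > 3pi/2) belongs to the next
            # cycle's forward sweep
            ci_eff = ci + 1 if phi > 1.5 * np.pi else ci
            key = "f"
        else:
            ci_eff = ci
            key = "b"
        slot = records.setdefault(ci_eff, {})
        if key not in slot or rate[p] > slot[key][2]:
            slot[key] = (times[p], phi_w, rate[p])

    out: list[PhaseRecord] = []
    for ci in sorted(records):
        slot = records[ci]
        tf, phif, rf = slot.get("f", (np.nan, np.nan, np.nan))
        tb, phib, rb = slot.get("b", (np.nan, np.nan, np.nan))
        t_ref = tf if np.isfinite(tf) else tb
        x_norm = np.nan
        h = np.nan
        if input_center is not None and np.isfinite(t_ref):
            xin = float(np.interp(t_ref, times, input_center))
            x_norm = (xin - neuron_pos) / (5 * a)
        if z is not None and np.isfinite(t_ref):
            h = float(np.interp(t_ref, times, z)) - neuron_pos
        out.append(
            PhaseRecord(ci, tf, tb, phif, phib, rf, rb, x_norm, h)
        )
    return out


def phase_shift_stage(
    records: list[PhaseRecord],
    margin: float = 0.15,
    rate_floor_frac: float = 0.3,
) -> list[PhaseRecord]:
    """Records from the phase-shift stage of the field traversal.

    The entry and departure stages pin the forward phase near +pi/2 and
    -pi/2; the shift stage is everything in between, identified as cycles
    whose forward phase lies at least ``margin`` rad inside the plateaus
    AND whose forward peak is strong (the bump actually crosses the cell
    there, so the peak rate is near its traversal maximum; weak tail peaks
    are entry/departure remnants, not shift-stage firing).
    """
    rmax = max(
        (r.peak_rate_f for r in records if np.isfinite(r.peak_rate_f)),
        default=0.0,
    )
    sel = [
        rec
        for rec in records
        if np.isfinite(rec.phi_f)
        and (-np.pi / 2 + margin) < rec.phi_f < (np.pi / 2 - margin)
        and rec.peak_rate_f >= rate_floor_frac * rmax
    ]
    return sel


def classify_modality(
    records: list[PhaseRecord], height_ratio_floor: float = 0.1
) -> str:
    """Bimodal vs unimodal firing from phase-shift-stage peak heights.

    A cell is bimodal when its backward (procession) peaks are not
    negligible next to the forward ones: median backward/forward peak-rate
    ratio >= ``height_ratio_floor`` over phase-shift-stage cycles.  There is
    no sharp biological boundary; the floor is a reporting convention.
    """
    stage = phase_shift_stage(records)
    if not stage:
        stage = records
    ratios = []
    for rec in stage:
        if not np.isfinite(rec.peak_rate_f) or rec.peak_rate_f <= 0:
            continue
        back = rec.peak_rate_b if np.isfinite(rec.peak_rate_b) else 0.0
        ratios.append(back / rec.peak_rate_f)
    if not ratios:
        return "unimodal"
    return "bimodal" if float(np.median(ratios)) >= height_ratio_floor else "unimodal"


@dataclass(frozen=True)
class PhaseHeatmap:
    """Probability mass over (normalized field position, unwrapped phase).

    ``p`` has shape (n_x_bins, n_phase_bins); rows span x_norm in [-1, 1],
    columns span phase in (0, 720) degrees (two concatenated theta cycles,
    odd/even cycles filling the first/second turn).  Mass sums to 1.
    """

    x_edges: np.ndarray
    phase_edges_deg: np.ndarray
    p: np.ndarray


def phase_position_heatmap(
    trace: SimulationTrace,
    grid: NeuronGrid,
    cycles: ThetaCycles,
    *,
    a: float,
    n_x_bins: int = 40,
    n_phase_bins: int = 72,
) -> PhaseHeatmap:
    """Accumulate firing-rate mass over field position and theta phase.

    For every neuron whose field (center x_i, halfwidth 2.5 a) contains the
    animal, its rate at time t is added at (x_norm, phase) where x_norm =
    (x_animal - x_i)/(5 a) and the phase axis unwraps two successive cycles
    onto (0, 720) degrees.  Normalized to total mass 1.
    """
    times = trace.times
    phi_raw, cyc = cycles.phase_at(times)
    valid_t = cyc >= 0
    xin = trace.input_center
    pos = grid.positions
    x_edges = np.linspace(-1, 1, n_x_bins + 1)
    phase_edges = np.linspace(0, 720, n_phase_bins + 1)
    H = np.zeros((n_x_bins, n_phase_bins))
    phase_deg = np.degrees(phi_raw) + 360.0 * (cyc % 2)
    for i, xi in enumerate(pos):
        d = grid.wrap(xin - xi) if grid.topology == "ring" else xin - xi
        x_norm = d / (5 * a)
        sel = valid_t & (np.abs(x_norm) <= 1)
        if not sel.any():
            continue
        h, _, _ = np.histogram2d(
            x_norm[sel],
            phase_deg[sel],
            bins=(x_edges, phase_edges),
            weights=trace.r_t[sel, i],
        )
        H += h
    total = H.sum()
    if total > 0:
        H /= total
    return PhaseHeatmap(x_edges=x_edges, phase_edges_deg=phase_edges, p=H)


def autocorrelogram(
    f: np.ndarray, dt_ms: float, max_lag_ms: float = 500.0, normalize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-window rate autocorrelogram (f*f)(lag) = dt * sum f(t) f(t+lag).

    Symmetric in the lag with its maximum at zero; optionally peak-
    normalized.  Returns (lags_ms, values).
    """
    return crosscorrelogram(f, f, dt_ms, max_lag_ms, normalize)


def crosscorrelogram(
    f: np.ndarray,
    g: np.ndarray,
    dt_ms: float,
    max_lag_ms: float = 500.0,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-window crosscorrelogram (f*g)(lag) = dt * sum f(t) g(t+lag).

    The biased (unnormalized-by-overlap) estimator on the recorded window;
    satisfies (f*g)(lag) = (g*f)(-lag).
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError("traces must share the time axis")
    n = len(f)
    nlag = min(int(round(max_lag_ms / dt_ms)), n - 1)
    full = signal.correlate(g, f, mode="full") * dt_ms  # index n-1 = zero lag
    lags = np.arange(-nlag, nlag + 1)
    vals = full[n - 1 - nlag : n + nlag]
    if normalize and np.abs(vals).max() > 0:
        vals = vals / np.abs(vals).max()
    return lags * dt_ms, vals


def rate_spectrum(
    rate: np.ndarray,
    dt_ms: float,
    min_cycles: int = 5,
    band_hz: tuple[float, float] = (1.0, 30.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Power spectrum of a mean-removed rate trace, with its peaks.

    Returns (freqs_hz, power, peak_freqs_hz) where the peaks are local
    spectral maxima inside ``band_hz`` sorted by descending power.  Raises
    on traces shorter than ``min_cycles`` putative theta cycles (125 ms).
    """
    rate = np.asarray(rate, dtype=float)
    T_ms = len(rate) * dt_ms
    if T_ms < min_cycles * 125.0:
        raise ValueError(
            f"trace of {T_ms:.0f} ms too short for spectral analysis"
        )
    fs = 1000.0 / dt_ms
    x = rate - rate.mean()
    freqs, power = signal.periodogram(x, fs=fs, window="hann")
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    fb, pb = freqs[sel], power[sel]
    pk, _ = signal.find_peaks(pb, prominence=pb.max() * 0.02)
    order = np.argsort(pb[pk])[::-1]
    return freqs, power, fb[pk][order]


def sweep_lengths(
    s: np.ndarray, times: np.ndarray, cycles: ThetaCycles
) -> np.ndarray:
    """Per-cycle maximal forward excursion of the bump beyond the input (m)."""
    s = np.asarray(s, dtype=float)
    _, cyc = cycles.phase_at(np.asarray(times, dtype=float))
    out = np.full(cycles.n, np.nan)
    for ci in range(cycles.n):
        sel = cyc == ci
        if sel.any():
            out[ci] = np.nanmax(s[sel])
    return out


def bump_height_by_window(
    trace: SimulationTrace, cycles: ThetaCycles
) -> tuple[float, float]:
    """Mean bump height in forward vs backward windows.

    Forward = phases (-pi/2, pi/2] (bump sweeping ahead), backward =
    (pi/2, 3 pi/2].  The forward mean exceeds the backward one whenever
    adaptation asymmetrically suppresses the return sweep.
    """
    phi_raw, cyc = cycles.phase_at(trace.times)
    valid = cyc >= 0
    phi_w = _wrap_forward(phi_raw)
    fwd = valid & (phi_w <= np.pi / 2)
    bwd = valid & (phi_w > np.pi / 2)
    if not fwd.any() or not bwd.any():
        raise NonOscillatoryTraceError("windows undefined without oscillation")
    return float(trace.bump_height[fwd].mean()), float(trace.bump_height[bwd].mean())
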