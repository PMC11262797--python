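"""Scripted experiments on top of the simulator.

Each protocol builds its own grid and input trajectory, runs the
deterministic simulation, and reduces the trace to the quantities of
interest: regime maps over (m, alpha), phase records around transient
silencing, speed sweeps of single-cell vs bump oscillation frequency, and
the T-maze sweep-cycling experiment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .analysis import NonOscillatoryTraceError, ThetaCycles
from .environments import NeuronGrid, TMazeGeometry, build_linear_track, build_tmaze, tmaze_input_path
from .model import SimulationTrace, simulate
from .params import ModelParams, get_preset

__all__ = [
    "run_phase_diagram",
    "run_silencing",
    "run_speed_sweep",
    "run_tmaze",
    "linear_track_run",
    "probe_phase_curve",
    "trace_checksum",
]


def trace_checksum(trace: SimulationTrace) -> str:
    """Content hash of a trace for regression comparison across runs."""
    h = hashlib.sha256()
    for arr in (trace.times, trace.z, trace.s, trace.bump_height):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def linear_track_run(
    params: ModelParams,
    *,
    duration_ms: float | None = None,
    probe_x: float | None = None,
    n_neurons: int = 512,
    silence_windows=(),
    stride: int = 5,
) -> tuple[SimulationTrace, NeuronGrid, np.ndarray | None]:
    """Simulate the ring track; optionally return a probe neuron's rate trace.

    The probe is the neuron nearest ``probe_x``; its rate history comes from
    the stored population rates.
    """
    grid = build_linear_track(n_neurons, params.rho)
    trace = simulate(
        params,
        grid,
        duration_ms=duration_ms,
        silence_windows=silence_windows,
        stride=stride,
    )
    probe = None
    if probe_x is not None:
        idx = int(np.argmin(np.abs(grid.wrap(grid.positions - probe_x))))
        probe = trace.r_t[:, idx]
    return trace, grid, probe


def _classify_point(
    s: np.ndarray, times: np.ndarray, osc_floor: float, settle_ms: float = 700.0
) -> tuple[str, float]:
    """Simulation-based regime label for one (m, alpha) grid point.

    Only the settled tail of the trace is classified; the first
    ``settle_ms`` carry the relaxation onto the attractor.
    """
    tail = times >= times[0] + settle_ms
    s, times = s[tail], times[tail]
    # traveling wave: the bump escapes the input and laps the ring, so the
    # wrapped displacement spends much of its time far from zero
    if np.mean(np.abs(s)) > 1.0:
        return "traveling_wave", np.nan
    try:
        cycles = analysis.segment_cycles(s, times, min_amplitude=osc_floor)
    except NonOscillatoryTraceError:
        return "smooth_tracking", np.nan
    return "oscillatory_tracking", cycles.mean_freq


def run_phase_diagram(
    m_values: np.ndarray,
    alpha_values: np.ndarray,
    *,
    base: ModelParams | None = None,
    duration_ms: float = 3000.0,
    n_neurons: int = 512,
    osc_floor: float | None = None,
) -> dict:
    """Simulated regime label and oscillation frequency over an (m, alpha) grid.

    The oscillation floor separating smooth from oscillatory tracking is
    3x the residual wobble of an adaptation-free (m=0) reference run at the
    largest alpha scanned, unless given explicitly.
    """
    base = base or get_preset("linear_default")
    grid = build_linear_track(n_neurons, base.rho)
    if osc_floor is None:
        ref = simulate(
            base.replace(m=0.0, alpha=float(np.max(alpha_values))),
            grid,
            duration_ms=min(duration_ms, 1500.0),
        )
        tail = ref.s[len(ref.s) // 3 :]
        osc_floor = max(3.0 * float(np.std(tail)), 0.005)
    labels = np.empty((len(m_values), len(alpha_values)), dtype=object)
    freqs = np.full((len(m_values), len(alpha_values)), np.nan)
    for i, m in enumerate(m_values):
        for j, al in enumerate(alpha_values):
            p = base.replace(m=float(m), alpha=float(al))
            try:
                tr = simulate(p, grid, duration_ms=duration_ms)
            except Exception:
                labels[i, j] = "diverged"
                continue
            lab, fr = _classify_point(tr.s, tr.times, osc_floor)
            labels[i, j] = lab
            freqs[i, j] = fr
    return {
        "m_values": np.asarray(m_values, dtype=float),
        "alpha_values": np.asarray(alpha_values, dtype=float),
        "labels": labels,
        "freqs": freqs,
        "osc_floor": osc_floor,
    }


def probe_phase_curve(
    trace: SimulationTrace,
    probe_rate: np.ndarray,
    *,
    probe_x: float,
    a: float,
    cycles: ThetaCycles | None = None,
    rate_floor_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Forward-phase vs normalized-field-position curve of a probe neuron.

    Returns (x_norm, phi_f, records) for cycles with a forward peak, sorted
    by position.  Peaks below ``rate_floor_frac`` of the strongest forward
    peak are dropped: a phase read off near-zero firing is not a phase the
    cell expresses.
    """
    if cycles is None:
        cycles = analysis.segment_cycles(trace.s, trace.times)
    records = analysis.phase_record(
        probe_rate,
        trace.times,
        cycles,
        input_center=trace.input_center,
        neuron_pos=probe_x,
        z=trace.z,
        a=a,
    )
    rmax = max(
        (r.peak_rate_f for r in records if np.isfinite(r.peak_rate_f)),
        default=0.0,
    )
    pts = [
        (r.x_norm, r.phi_f)
        for r in records
        if np.isfinite(r.phi_f)
        and np.isfinite(r.x_norm)
        and abs(r.x_norm) <= 1.0
        and r.peak_rate_f >= rate_floor_frac * rmax
    ]
    pts.sort()
    if not pts:
        return np.array([]), np.array([]), records
    xs, ps = map(np.array, zip(*pts))
    return xs, ps, records


def run_silencing(
    *,
    preset: str = "unimodal",
    silence_start_ms: float,
    silence_durations_ms: tuple[float, ...] = (100.0,),
    probe_x: float = 2.0,
    duration_ms: float = 2500.0,
    overrides: dict | None = None,
) -> dict:
    """Transient-inactivation experiment around a probe neuron's field.

    Runs one control simulation and one per silencing duration (population
    rate clamped to zero in the window), then compares the forward-phase vs
    position curves after resumption.  The claim under test is positional:
    after any silencing the phase continues from the animal's new location,
    so the curves should superimpose.
    """
    params = get_preset(preset, **(overrides or {}))
    control, grid, probe = linear_track_run(
        params, duration_ms=duration_ms, probe_x=probe_x
    )
    xc, pc, _ = probe_phase_curve(control, probe, probe_x=probe_x, a=params.a)
    out = {"control": (xc, pc), "silenced": {}, "max_phase_diff": {}}
    for dur in silence_durations_ms:
        windows = [(silence_start_ms, dur)] if dur > 0 else []
        tr, _, pr = linear_track_run(
            params, duration_ms=duration_ms, probe_x=probe_x,
            silence_windows=windows,
        )
        cycles = analysis.segment_cycles(tr.s, tr.times)
        xs, ps, recs = probe_phase_curve(
            tr, pr, probe_x=probe_x, a=params.a, cycles=cycles
        )
        # a cycle whose span overlaps the dead window has no defined phase:
        # its boundaries bridge a gap in the oscillation
        t_resume = silence_start_ms + dur
        bad = {
            ci
            for ci in range(cycles.n)
            if cycles.boundaries[ci] < t_resume
            and cycles.boundaries[ci + 1] > silence_start_ms
        }
        keep_pts = sorted(
            (r.x_norm, r.phi_f)
            for r in recs
            if np.isfinite(r.phi_f)
            and np.isfinite(r.x_norm)
            and abs(r.x_norm) <= 1.0
            and r.cycle_index not in bad
            and r.peak_rate_f
            >= 0.05 * max(q.peak_rate_f for q in recs if np.isfinite(q.peak_rate_f))
        )
        if keep_pts:
            xs, ps = map(np.array, zip(*keep_pts))
        # position-matched comparison on post-resumption cycles, at
        # positions the control curve actually covers
        x_resume = (
            float(np.interp(t_resume, tr.times, tr.input_center)) - probe_x
        ) / (5 * params.a)
        sel = (xs > x_resume) & (xs >= xc.min()) & (xs <= xc.max())
        diffs = np.abs(np.interp(xs[sel], xc, pc) - ps[sel]) if sel.any() else np.array([])
        out["silenced"][dur] = (xs, ps)
        out["max_phase_diff"][dur] = float(diffs.max()) if diffs.size else np.nan
    return out


def run_speed_sweep(
    speed_list=(0.75, 1.0, 1.25, 1.5, 1.75, 2.0),
    *,
    preset: str = "unimodal",
    probe_x: float = 2.0,
    overrides: dict | None = None,
) -> dict:
    """Bump baseline frequency vs single-cell spectral peaks across speeds.

    For each running speed, the probe's rate trace during its field
    traversal is spectrally analyzed; phase precession adds half a cycle
    over the traversal, so the cell peak sits above the bump baseline by an
    amount growing with speed (and for bimodal cells a second, procession
    peak sits below it).
    """
    params0 = get_preset(preset, **(overrides or {}))
    rows = []
    for v in speed_list:
        params = params0.replace(v_ext=float(v))
        # simulate long enough to cross the field centered at probe_x
        field = 2.5 * params.a
        t_end = (probe_x + field + 0.3) / v * 1000.0
        trace, grid, probe = linear_track_run(params, duration_ms=t_end, probe_x=probe_x)
        cycles = analysis.segment_cycles(trace.s, trace.times)
        base_freq = cycles.mean_freq
        # restrict to the traversal window
        xin = trace.input_center
        sel = np.abs(xin - probe_x) <= field
        dt = trace.dt_sample
        _, _, peaks = analysis.rate_spectrum(probe[sel], dt, min_cycles=3)
        above = peaks[peaks > base_freq]
        below = peaks[peaks < base_freq]
        rows.append(
            {
                "v_ext": v,
                "baseline_hz": base_freq,
                "cell_peak_hz": float(peaks[0]) if len(peaks) else np.nan,
                "precession_hz": float(above[0]) if len(above) else np.nan,
                "procession_hz": float(below[0]) if len(below) else np.nan,
            }
        )
    vs = np.array([r["v_ext"] for r in rows])
    pre = np.array([r["precession_hz"] - r["baseline_hz"] for r in rows])
    pro = np.array([r["procession_hz"] - r["baseline_hz"] for r in rows])
    ok_pre = np.isfinite(pre)
    ok_pro = np.isfinite(pro)
    slope_pre = float(np.polyfit(vs[ok_pre], pre[ok_pre], 1)[0]) if ok_pre.sum() > 1 else np.nan
    slope_pro = float(np.polyfit(vs[ok_pro], pro[ok_pro], 1)[0]) if ok_pro.sum() > 1 else np.nan
    return {"rows": rows, "slope_precession": slope_pre, "slope_procession": slope_pro}


@dataclass
class TMazeResult:
    trace: SimulationTrace
    grid: NeuronGrid
    geometry: TMazeGeometry
    cycles: ThetaCycles
    occupancy: dict[str, np.ndarray]  # center/left/right rate mass per sample
    arm_per_cycle: list[str]  # "L" | "R" | "-" for each cycle
    progress: np.ndarray  # geodesic bump lead over the input (m)


def _maze_progress(
    z: np.ndarray, centers: np.ndarray, geo: TMazeGeometry
) -> np.ndarray:
    """Geodesic lead of the decoded bump over the input along the maze (m).

    On the central arm this is the y-lead; once the bump is in a side arm it
    is the lead to the junction plus the lateral excursion past the center
    line of the maze.
    """
    zx, zy = z[:, 0], z[:, 1]
    cy = centers[:, 1]
    in_arm = np.abs(zx) > geo.central_width / 2
    lead = np.where(
        in_arm,
        (geo.central_length - cy) + (np.abs(zx) - geo.central_width / 2),
        zy - cy,
    )
    return lead


def run_tmaze(
    *,
    geometry: TMazeGeometry | None = None,
    overrides: dict | None = None,
    duration_ms: float | None = None,
    stride: int = 5,
) -> TMazeResult:
    """T-maze sweep-cycling experiment.

    The input moves up the central arm at v_ext and clamps at the junction;
    theta cycles are segmented from the geodesic bump lead, and each cycle
    is labeled by the outer arm (if any) receiving its maximal lateral
    excursion.  Delayed adaptation makes successive sweeps visit the two
    arms in alternation once the input is near the junction.
    """
    geo = geometry or TMazeGeometry()
    params = get_preset("tmaze", **(overrides or {}))
    grid = build_tmaze(geo, a=params.a)
    T = duration_ms if duration_ms is not None else params.T_total * 1000.0

    def path(t_ms: float) -> np.ndarray:
        return tmaze_input_path(t_ms, params.v_ext, geo)

    trace = simulate(
        params, grid, duration_ms=T, input_path=path, stride=stride
    )
    progress = _maze_progress(trace.z, trace.input_center, geo)
    cycles = analysis.segment_cycles(progress, trace.times)

    pos = grid.positions
    half_w = geo.central_width / 2
    left = pos[:, 0] < -half_w
    right = pos[:, 0] > half_w
    center = ~(left | right)
    occupancy = {
        "center": trace.r_t[:, center].sum(axis=1),
        "left": trace.r_t[:, left].sum(axis=1),
        "right": trace.r_t[:, right].sum(axis=1),
    }

    _, cyc = cycles.phase_at(trace.times)
    zx = trace.z[:, 0]
    arm_per_cycle: list[str] = []
    for ci in range(cycles.n):
        sel = cyc == ci
        if not sel.any():
            arm_per_cycle.append("-")
            continue
        lmax = float(np.nanmax(np.where(sel, -zx, -np.inf)))
        rmax = float(np.nanmax(np.where(sel, zx, -np.inf)))
        if max(lmax, rmax) <= half_w:
            arm_per_cycle.append("-")
        else:
            arm_per_cycle.append("L" if lmax >= rmax else "R")
    return TMazeResult(trace, grid, geo, cycles, occupancy, arm_per_cycle, progress)
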