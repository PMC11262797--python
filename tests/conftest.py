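"""Shared fixtures: expensive simulation runs are session-scoped so the
oscillatory-tracking trace, its cycles and probe records are computed once."""

from __future__ import annotations

import numpy as np
import pytest

import thetasweep as ts
from thetasweep import analysis, protocols


@pytest.fixture(scope="session")
def default_params():
    return ts.get_preset("linear_default")


@pytest.fixture(scope="session")
def ring_grid(default_params):
    return ts.build_linear_track(512, default_params.rho)


@pytest.fixture(scope="session")
def bimodal_run():
    """2.5 s oscillatory-tracking run with a probe neuron at x = 2 m."""
    params = ts.get_preset("bimodal")
    trace, grid, probe = protocols.linear_track_run(
        params, duration_ms=2500.0, probe_x=2.0
    )
    cycles = analysis.segment_cycles(trace.s, trace.times)
    return {
        "params": params,
        "trace": trace,
        "grid": grid,
        "probe": probe,
        "probe_x": 2.0,
        "cycles": cycles,
    }


@pytest.fixture(scope="session")
def bimodal_records(bimodal_run):
    run = bimodal_run
    return analysis.phase_record(
        run["probe"],
        run["trace"].times,
        run["cycles"],
        input_center=run["trace"].input_center,
        neuron_pos=run["probe_x"],
        z=run["trace"].z,
        a=run["params"].a,
    )
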