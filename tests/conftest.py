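"""Shared fixtures.

Simulation-backed fixtures are session-scoped: the baseline steady state
and a handful of reference windows are reused by many tests to keep the
suite inside a sensible wall-clock budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from cmcal import ConductanceSet, StimulusSpec, Trace, simulate
from cmcal.simulation import derive_initial_state


@pytest.fixture(scope="session")
def x0():
    """Baseline steady state (10-minute unstimulated run, cached)."""
    return derive_initial_state()


@pytest.fixture(scope="session")
def baseline_window(x0):
    """Final 30 s of a 120 s baseline run at 1 ms sampling."""
    return simulate(ConductanceSet(), duration_ms=120_000, x0=x0,
                    dt_out=1.0, record_start=90_000)


@pytest.fixture(scope="session")
def baseline_window_fine(x0):
    """Final 10 s of a 60 s baseline run at 0.1 ms sampling."""
    return simulate(ConductanceSet(), duration_ms=60_000, x0=x0,
                    dt_out=0.1, record_start=50_000)


@pytest.fixture(scope="session")
def paced_window(x0):
    """Final 5 s of a 60 s run paced at 1 Hz, 0.1 ms sampling."""
    return simulate(ConductanceSet(), stim=StimulusSpec.paced(1.0),
                    duration_ms=60_000, x0=x0, dt_out=0.1,
                    record_start=55_000)


def synthetic_ap_train(period_ms: float = 1000.0, n_beats: int = 5,
                       dt: float = 1.0, apd: float = 300.0,
                       v_rest: float = -75.0, v_peak: float = 25.0,
                       lead_ms: float = 100.0) -> Trace:
    """Idealized AP train: fast upstroke, linear repolarization."""
    total = lead_ms + n_beats * period_ms
    t = np.arange(0.0, total + dt / 2, dt)
    v = np.full_like(t, v_rest)
    amp = v_peak - v_rest
    for k in range(n_beats):
        t_up = lead_ms + k * period_ms
        rise = (t >= t_up) & (t < t_up + 5.0)
        v[rise] = v_rest + amp * (t[rise] - t_up) / 5.0
        fall = (t >= t_up + 5.0) & (t < t_up + 5.0 + apd)
        v[fall] = v_peak - amp * (t[fall] - t_up - 5.0) / apd
    ca = (v - v_rest) / amp * 3e-4 + 2e-4
    return Trace(t, v, ca)
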