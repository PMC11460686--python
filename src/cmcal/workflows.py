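"""High-level experiment workflows shared by the CLI, tests and scripts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import CalibrationRun, GAConfig, ga_run
from .dataset import draw_multipliers, spontaneous_rate
from .features import detect_beats
from .protocol import (Protocol, TraceSet, baseline_condition,
                       normalize_traces, optimized_protocol, run_protocol)
from .simulation import derive_initial_state
from .types import ConductanceSet

__all__ = ["population_phenotypes", "make_recovery_target",
           "parameter_recovery", "select_dataset_cells",
           "FAST_RECOVERY_PARAMS"]

#: The four high-sensitivity parameters used in scaled-down recovery runs.
FAST_RECOVERY_PARAMS = ("g_Kr", "g_CaL", "g_Na", "g_K1")


def population_phenotypes(
    n: int,
    spread: float = 0.2,
    seed: int = 0,
    equil_ms: float = 60_000.0,
    window_ms: float = 10_000.0,
) -> tuple[list[ConductanceSet], pd.DataFrame]:
    """Baseline phenotypes (APD90, CaT amplitude, rate) of a random population.

    Cells that fail to simulate or do not beat get NaN phenotypes; they stay
    in the table so that callers can couple rows back to the population.
    """
    cells = draw_multipliers(n, spread=spread, seed=seed)
    x0 = derive_initial_state()
    p = Protocol((baseline_condition(equil_ms + window_ms),),
                 window_ms=window_ms, dt_out=1.0)
    rows = []
    for c in cells:
        ts = run_protocol(c, p, x0)
        row = {"apd90_ms": np.nan, "cat_amplitude_mM": np.nan, "rate_hz": np.nan}
        if not ts.failed:
            tr = ts.traces[0]
            beats = detect_beats(tr)
            apd = beats["apd90_ms"].to_numpy(dtype=float)
            ca_amp = beats["ca_amplitude"].to_numpy(dtype=float)
            ok = np.isfinite(apd)
            if ok.sum() >= 2:
                row["apd90_ms"] = float(np.median(apd[ok]))
                row["cat_amplitude_mM"] = float(np.median(ca_amp[ok]))
            r = spontaneous_rate(tr)
            row["rate_hz"] = np.nan if r is None else r
        rows.append(row)
    return cells, pd.DataFrame(rows)


def select_dataset_cells(
    n_cells: int = 4,
    spread: float = 0.2,
    seed: int = 0,
    duration_ms: float = 300_000.0,
    window_ms: float = 30_000.0,
    batch: int = 16,
    rate_band: tuple[float, float] = (0.3, 1.0),
) -> list[ConductanceSet]:
    """Draw, filter and randomly select the dataset's model cells.

    A cell qualifies when its spontaneous rate under the unperturbed
    baseline lies in ``rate_band`` *and* its baseline rhythm classifies as
    regular ("none") — arrhythmia-susceptibility thresholds are defined as
    the block level that *induces* arrhythmic dynamics, which presupposes
    a non-arrhythmic baseline.  Cells are drawn in seeded batches until
    ``n_cells`` qualify; the final pick among qualifiers is a seeded
    random choice.
    """
    from .features import classify_arrhythmia
    from .protocol import run_protocol as _run
    x0 = derive_initial_state()
    p = Protocol((baseline_condition(duration_ms),), window_ms=window_ms,
                 dt_out=1.0)
    kept: list[ConductanceSet] = []
    offset = 0
    while len(kept) < n_cells and offset < 20 * batch:
        for c in draw_multipliers(batch, spread=spread, seed=seed + offset):
            ts = _run(c, p, x0)
            if ts.failed:
                continue
            rate = spontaneous_rate(ts.traces[0])
            if rate is None or not rate_band[0] <= rate <= rate_band[1]:
                continue
            if classify_arrhythmia(ts.traces[0],
                                   baseline_rate=rate) != "none":
                continue
            kept.append(c)
        offset += batch
    if len(kept) < n_cells:
        raise RuntimeError("population filter kept too few cells")
    rng = np.random.default_rng(seed + 10_007)
    idx = rng.choice(len(kept), size=n_cells, replace=False)
    return [kept[i] for i in idx]


def make_recovery_target(
    truth: ConductanceSet,
    condition_s: float = 65.0,
    window_ms: float = 5_000.0,
    normalized: bool = True,
    dt_out: float = 0.1,
) -> tuple[TraceSet, Protocol]:
    """Simulate the optimized 3-condition protocol for a known cell.

    ``condition_s`` is the per-condition duration (pre-equilibration plus
    the recorded window).
    """
    proto = optimized_protocol(duration_ms=condition_s * 1000.0,
                               window_ms=window_ms, dt_out=dt_out)
    x0 = derive_initial_state()
    target = run_protocol(truth, proto, x0)
    if target.failed:
        raise RuntimeError("ground-truth cell failed to simulate")
    if normalized:
        target = normalize_traces(target)
    return target, proto


def parameter_recovery(
    truth: ConductanceSet,
    free_parameters: tuple[str, ...] = FAST_RECOVERY_PARAMS,
    normalized: bool = True,
    population_size: int = 50,
    generations: int = 10,
    condition_s: float = 65.0,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[CalibrationRun, TraceSet]:
    """Scaled-down parameter-recovery experiment on a synthetic cell.

    Generates the (optionally normalized) optimized-protocol target from
    the known truth, then fits the requested free parameters with reduced
    GA settings.  Returns the calibration run and the target.
    """
    target, proto = make_recovery_target(truth, condition_s=condition_s,
                                         normalized=normalized)
    cfg = GAConfig(population_size=population_size, generations=generations,
                   free_parameters=tuple(free_parameters), seed=seed,
                   n_jobs=n_jobs)
    run = ga_run(target, proto, cfg)
    return run, target
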