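"""Synthetic-population generation and the in-silico calibration test-bed.

A heterogeneous "population" of model cells is created by drawing an
independent log-normal multiplier for each of the 16 maximal-conductance
parameters (median multiplier 1, spread = standard deviation of the
underlying normal in natural-log space).  The population is simulated under
the physiological, unperturbed condition and filtered to cells whose
spontaneous beating frequency falls in a physiological band (0.3–1.0 Hz by
default).  A small number of filtered cells is then simulated under the
full condition roster to build a dataset of steady-state AP/CaT windows
with known ground-truth conductances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import detect_beats
from .protocol import (Condition, Protocol, TraceSet, baseline_condition,
                       condition_library, normalize_traces, run_protocol)
from .simulation import derive_initial_state
from .types import CONDUCTANCE_NAMES, ConductanceSet, Trace

__all__ = [
    "draw_multipliers", "spontaneous_rate", "filter_population",
    "build_dataset", "InSilicoDataset", "simulate_population_rates",
]

SPREAD_DEFAULT = 0.2          # log-normal spread of the population
RATE_BAND_DEFAULT = (0.3, 1.0)  # Hz, physiological automaticity band


def draw_multipliers(n: int, spread: float = SPREAD_DEFAULT,
                     seed: int | None = None,
                     log_base: str = "natural") -> list[ConductanceSet]:
    """Draw ``n`` random conductance-multiplier sets.

    Each multiplier is ``exp(z)`` (or ``2**z`` for ``log_base='log2'``) with
    ``z ~ Normal(0, spread)``, independent across the 16 parameters and
    across cells, so the median multiplier is exactly 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, spread, size=(n, len(CONDUCTANCE_NAMES)))
    mult = np.exp(z) if log_base == "natural" else np.exp2(z)
    return [ConductanceSet(tuple(row)) for row in mult]


def spontaneous_rate(t: Trace) -> float | None:
    """Spontaneous beating frequency (Hz), or None for < 2 beats.

    Computed as (beat count - 1) divided by the span between the first and
    last upstroke, which is insensitive to partial beats at the window edges.
    """
    beats = detect_beats(t)
    if len(beats) < 2:
        return None
    ups = beats["upstroke_ms"].to_numpy(dtype=float)
    return 1000.0 * (len(ups) - 1) / (ups[-1] - ups[0])


def simulate_population_rates(
    cells: list[ConductanceSet],
    duration_ms: float = 300_000.0,
    window_ms: float = 30_000.0,
    x0: np.ndarray | None = None,
) -> list[float | None]:
    """Spontaneous rate of each cell under the unperturbed baseline."""
    x0 = derive_initial_state() if x0 is None else x0
    p = Protocol((baseline_condition(duration_ms),), window_ms=window_ms,
                 dt_out=1.0)
    rates: list[float | None] = []
    for c in cells:
        ts = run_protocol(c, p, x0)
        rates.append(None if ts.failed else spontaneous_rate(ts.traces[0]))
    return rates


def filter_population(cells: list[ConductanceSet],
                      rates: list[float | None],
                      f_min: float = RATE_BAND_DEFAULT[0],
                      f_max: float = RATE_BAND_DEFAULT[1]
                      ) -> list[ConductanceSet]:
    """Keep cells whose spontaneous rate lies in [f_min, f_max] (closed).

    Non-beating (None) cells are excluded.
    """
    return [c for c, r in zip(cells, rates)
            if r is not None and f_min <= r <= f_max]


@dataclass
class InSilicoDataset:
    """Per-cell x per-condition recorded windows with ground truth.

    ``entries[(cell_idx, label)]`` is a Trace (possibly flagged failed).
    """

    cells: list[ConductanceSet]
    conditions: dict[str, Condition]
    window_ms: float
    dt_out: float
    entries: dict[tuple[int, str], Trace] = field(default_factory=dict)
    normalized_entries: dict[tuple[int, str], Trace] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def trace_set(self, cell: int, labels: list[str],
                  normalized: bool = False) -> TraceSet:
        """Assemble a TraceSet for one cell over the given condition labels."""
        store = self.normalized_entries if normalized else self.entries
        conds = tuple(self.conditions[lab] for lab in labels)
        proto = Protocol(conds, window_ms=self.window_ms, dt_out=self.dt_out)
        traces = [store[(cell, lab)].copy() for lab in labels]
        return TraceSet(traces, protocol=proto, normalized=normalized,
                        source=self.cells[cell])

    # -- plain-text persistence: CSV per entry + a JSON manifest -----------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "window_ms": self.window_ms,
            "dt_out": self.dt_out,
            "meta": self.meta,
            "cells": [c.to_dict() for c in self.cells],
            "conditions": sorted(self.conditions),
            "entries": [],
        }
        for (i, lab), tr in self.entries.items():
            fname = f"cell{i}_{lab}.csv"
            pd.DataFrame({"time_ms": tr.t, "V": tr.V, "Cai": tr.Ca}).to_csv(
                d / fname, index=False)
            manifest["entries"].append(
                {"cell": i, "condition": lab, "file": fname,
                 "failed": bool(tr.failed)})
        from .protocol import _condition_to_dict
        manifest["condition_specs"] = {
            lab: _condition_to_dict(c) for lab, c in self.conditions.items()}
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory: str | Path) -> "InSilicoDataset":
        from .protocol import _condition_from_dict
        d = Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        conditions = {lab: _condition_from_dict(spec) for lab, spec
                      in manifest["condition_specs"].items()}
        ds = cls(
            cells=[ConductanceSet.from_dict(cd) for cd in manifest["cells"]],
            conditions=conditions,
            window_ms=manifest["window_ms"],
            dt_out=manifest["dt_out"],
            meta=manifest.get("meta", {}),
        )
        for e in manifest["entries"]:
            df = pd.read_csv(d / e["file"])
            tr = Trace(df["time_ms"].to_numpy(), df["V"].to_numpy(),
                       df["Cai"].to_numpy(), failed=e["failed"])
            ds.entries[(e["cell"], e["condition"])] = tr
            try:
                ts = normalize_traces(
                    TraceSet([tr.copy()]), mode="per-segment")
                ds.normalized_entries[(e["cell"], e["condition"])] = ts.traces[0]
            except ValueError:
                pass
        return ds


def build_dataset(
    cells: list[ConductanceSet],
    conditions: dict[str, Condition] | None = None,
    window_ms: float = 5_000.0,
    dt_out: float = 0.1,
    x0: np.ndarray | None = None,
    seed: int | None = None,
) -> InSilicoDataset:
    """Simulate every cell under every condition and store the windows.

    Each condition starts from the shared baseline steady state (conditions
    are stored individually here; multi-condition protocols with carry-over
    are re-simulated at calibration time from the same specs).  Failed
    simulations are stored as flagged traces, never dropped silently.
    Normalized copies are derived post hoc from the identical simulations.
    """
    conditions = conditions if conditions is not None else condition_library()
    x0 = derive_initial_state() if x0 is None else x0
    ds = InSilicoDataset(cells=list(cells), conditions=dict(conditions),
                         window_ms=window_ms, dt_out=dt_out,
                         meta={"seed": seed})
    for i, c in enumerate(ds.cells):
        for lab, cond in ds.conditions.items():
            p = Protocol((cond,), window_ms=window_ms, dt_out=dt_out)
            ts = run_protocol(c, p, x0)
            tr = ts.traces[0]
            tr.meta.pop("final_state", None)
            ds.entries[(i, lab)] = tr
            if not tr.failed:
                try:
                    ds.normalized_entries[(i, lab)] = normalize_traces(
                        TraceSet([tr.copy()])).traces[0]
                except ValueError:
                    pass
    return ds
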