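"""Multi-condition experimental protocols with state carry-over.

A :class:`Condition` is one experimental segment — an extracellular milieu,
optional pacing, a channel-block map and a duration.  A :class:`Protocol`
is an ordered list of conditions simulated sequentially: the final state of
each condition seeds the next, mimicking a dish that is re-perfused and
re-paced between acquisitions.  Only the trailing ``window_ms`` of each
condition (the quasi-steady-state part) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .simulation import simulate
from .types import BlockMap, ConductanceSet, ExtracellularMilieu, StimulusSpec, Trace

__all__ = [
    "Condition", "Protocol", "TraceSet", "run_protocol", "extract_window",
    "resample_uniform", "normalize_traces", "condition_library",
    "optimized_protocol", "baseline_condition", "protocol_from_yaml",
    "protocol_to_yaml",
]


@dataclass(frozen=True)
class Condition:
    """One experimental segment.

    ``duration_ms`` includes the recorded window: a 65 s condition with a
    5 s window means 60 s of (pre-)equilibration followed by 5 s of
    recording.
    """

    label: str = "baseline"
    milieu: ExtracellularMilieu = ExtracellularMilieu()
    stim: StimulusSpec | None = None
    blocks: dict = field(default_factory=dict)
    duration_ms: float = 300_000.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("condition duration must be positive")
        object.__setattr__(self, "blocks", BlockMap(self.blocks))


@dataclass(frozen=True)
class Protocol:
    """Ordered conditions plus recording parameters."""

    conditions: tuple[Condition, ...]
    window_ms: float = 5_000.0
    dt_out: float = 0.1

    def __post_init__(self) -> None:
        conds = tuple(self.conditions)
        if not conds:
            raise ValueError("protocol needs at least one condition")
        for c in conds:
            if c.duration_ms < self.window_ms:
                raise ValueError(
                    f"condition {c.label!r} shorter than the recorded window")
        object.__setattr__(self, "conditions", conds)

    def with_durations(self, duration_ms: float) -> "Protocol":
        """Same protocol with every condition truncated/extended to
        ``duration_ms`` (used for fast, scaled-down calibrations)."""
        return Protocol(
            tuple(replace(c, duration_ms=duration_ms) for c in self.conditions),
            window_ms=self.window_ms, dt_out=self.dt_out)


@dataclass
class TraceSet:
    """Per-condition recorded V/Ca segments — the calibration currency."""

    traces: list[Trace]
    protocol: Protocol | None = None
    normalized: bool = False
    source: ConductanceSet | None = None   # ground truth, if synthetic

    @property
    def failed(self) -> bool:
        return any(tr.failed for tr in self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def copy(self) -> "TraceSet":
        return TraceSet([tr.copy() for tr in self.traces], self.protocol,
                        self.normalized, self.source)


def run_protocol(c: ConductanceSet, p: Protocol, x0: np.ndarray,
                 method: str = "adaptive") -> TraceSet:
    """Simulate the protocol's conditions sequentially with state carry-over.

    Each recorded segment is the trailing window of its condition sampled at
    ``p.dt_out``.  All state variables (including ion concentrations) carry
    over across milieu changes; only the external parameters switch.  A
    failed condition flags the whole TraceSet failed (remaining conditions
    are not simulated).
    """
    traces: list[Trace] = []
    state = np.asarray(x0, dtype=float)
    for cond in p.conditions:
        tr = simulate(
            c, cond.milieu, cond.blocks, cond.stim,
            duration_ms=cond.duration_ms, x0=state, dt_out=p.dt_out,
            record_start=cond.duration_ms - p.window_ms, method=method)
        tr.meta["condition"] = cond.label
        traces.append(tr)
        if tr.failed:
            break
        state = tr.meta["final_state"]
    return TraceSet(traces, protocol=p, normalized=False, source=c)


def extract_window(t: Trace, window_ms: float) -> Trace:
    """Trailing window of a trace, time re-zeroed."""
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if t.duration + 1e-9 < window_ms:
        raise ValueError(
            f"trace of {t.duration:.1f} ms shorter than window {window_ms:.1f} ms")
    t0 = t.t[-1] - window_ms
    mask = t.t >= t0 - 1e-9
    out = Trace(t.t[mask] - t.t[mask][0], t.V[mask], t.Ca[mask],
                normalized=t.normalized, failed=t.failed, meta=dict(t.meta))
    return out


def resample_uniform(t: Trace, dt: float) -> Trace:
    """Linear interpolation onto a uniform grid spanning the original times."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tt = np.asarray(t.t, dtype=float)
    if len(tt) > 1 and np.any(np.diff(tt) <= 0):
        raise ValueError("time grid must be strictly increasing")
    n = int(np.floor((tt[-1] - tt[0]) / dt + 1e-9)) + 1
    grid = tt[0] + np.arange(n) * dt
    return Trace(grid, np.interp(grid, tt, t.V), np.interp(grid, tt, t.Ca),
                 normalized=t.normalized, failed=t.failed, meta=dict(t.meta))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise ValueError("cannot normalize a constant segment "
                         "(non-beating or failed recording)")
    return (x - lo) / (hi - lo)


def normalize_traces(ts: TraceSet, mode: str = "per-segment") -> TraceSet:
    """Min-max scale every segment's V and Ca to span [0, 1].

    ``per-segment``: each condition's V and Ca normalized independently —
    each recording treated as an independent fluorescence acquisition.
    ``global``: one min/max per signal across all segments.
    """
    if ts.failed:
        raise ValueError("cannot normalize a failed trace set")
    out = ts.copy()
    if mode == "per-segment":
        for tr in out.traces:
            tr.V = _minmax(tr.V)
            tr.Ca = _minmax(tr.Ca)
            tr.normalized = True
    elif mode == "global":
        v_all = np.concatenate([tr.V for tr in out.traces])
        c_all = np.concatenate([tr.Ca for tr in out.traces])
        v_lo, v_hi = v_all.min(), v_all.max()
        c_lo, c_hi = c_all.min(), c_all.max()
        if v_hi - v_lo <= 0 or c_hi - c_lo <= 0:
            raise ValueError("cannot normalize constant signals")
        for tr in out.traces:
            tr.V = (tr.V - v_lo) / (v_hi - v_lo)
            tr.Ca = (tr.Ca - c_lo) / (c_hi - c_lo)
            tr.normalized = True
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# Canonical condition / protocol library
# ---------------------------------------------------------------------------

def baseline_condition(duration_ms: float = 300_000.0) -> Condition:
    """Physiological, unperturbed condition: 1.8 mM Ca, spontaneous."""
    return Condition("baseline", ExtracellularMilieu(), None, {}, duration_ms)


def optimized_protocol(duration_ms: float = 300_000.0,
                       window_ms: float = 5_000.0,
                       dt_out: float = 0.1) -> Protocol:
    """The optimized 3-condition calibration protocol.

    1. hypo-calcemic buffer (1.0 mM Ca), spontaneous;
    2. physiological buffer (1.8 mM Ca), spontaneous;
    3. physiological buffer, 1.25 Hz pacing with 25% L-type Ca block.
    """
    conds = (
        Condition("low_ca", ExtracellularMilieu(Ca_o=1.0), None, {}, duration_ms),
        Condition("baseline", ExtracellularMilieu(), None, {}, duration_ms),
        Condition("paced_cal_block", ExtracellularMilieu(),
                  StimulusSpec.paced(1.25), {"I_CaL": 0.25}, duration_ms),
    )
    return Protocol(conds, window_ms=window_ms, dt_out=dt_out)


def condition_library(duration_ms: float = 300_000.0) -> dict[str, Condition]:
    """The 19-condition roster used to build the in-silico dataset.

    Families: buffer calcium (hypo / normal / hyper), pacing rates
    (spontaneous and 1–2 Hz), L-type calcium block levels, and mixed
    combinations.  Condition 19 is the physiological, unperturbed baseline.
    """
    lib: dict[str, Condition] = {}

    def add(label, ca=1.8, hz=None, blocks=None):
        lib[label] = Condition(
            label, ExtracellularMilieu(Ca_o=ca),
            StimulusSpec.paced(hz) if hz else None,
            blocks or {}, duration_ms)

    # buffer calcium family (spontaneous)
    add("ca_1.0", ca=1.0)
    add("ca_2.5", ca=2.5)
    # pacing family (physiological buffer)
    add("pace_1.0", hz=1.0)
    add("pace_1.25", hz=1.25)
    add("pace_1.5", hz=1.5)
    add("pace_2.0", hz=2.0)
    # L-type calcium block family
    add("cal_25", blocks={"I_CaL": 0.25})
    add("cal_50", blocks={"I_CaL": 0.50})
    # mixed: calcium x pacing
    add("ca_1.0_pace_1.0", ca=1.0, hz=1.0)
    add("ca_1.0_pace_2.0", ca=1.0, hz=2.0)
    add("ca_2.5_pace_1.0", ca=2.5, hz=1.0)
    # mixed: pacing x block
    add("pace_1.25_cal_25", hz=1.25, blocks={"I_CaL": 0.25})
    add("pace_1.0_cal_50", hz=1.0, blocks={"I_CaL": 0.50})
    # mixed: calcium x block
    add("ca_1.0_cal_25", ca=1.0, blocks={"I_CaL": 0.25})
    add("ca_2.5_cal_25", ca=2.5, blocks={"I_CaL": 0.25})
    # held-out validation family: rapid delayed rectifier block
    add("kr_30", blocks={"I_Kr": 0.30})
    add("kr_30_pace_1.0", hz=1.0, blocks={"I_Kr": 0.30})
    add("k1_30", blocks={"I_K1": 0.30})
    # physiological, unperturbed baseline (condition 19)
    add("baseline")
    assert len(lib) == 19
    return lib


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _condition_to_dict(c: Condition) -> dict:
    return {
        "label": c.label,
        "ca_o": c.milieu.Ca_o, "na_o": c.milieu.Na_o, "k_o": c.milieu.K_o,
        "pacing_hz": (1000.0 / c.stim.period_ms) if c.stim else None,
        "stim_amplitude": c.stim.amplitude if c.stim else None,
        "stim_width_ms": c.stim.width_ms if c.stim else None,
        "blocks": dict(c.blocks),
        "duration_s": c.duration_ms / 1000.0,
    }


def _condition_from_dict(d: dict) -> Condition:
    hz = d.get("pacing_hz")
    stim = None
    if hz:
        stim = StimulusSpec.paced(hz, amplitude=d.get("stim_amplitude") or 60.0,
                                  width_ms=d.get("stim_width_ms") or 1.0)
    return Condition(
        d.get("label", "condition"),
        ExtracellularMilieu(Na_o=d.get("na_o", 151.0),
                            Ca_o=d.get("ca_o", 1.8),
                            K_o=d.get("k_o", 5.4)),
        stim, d.get("blocks") or {},
        float(d.get("duration_s", 300.0)) * 1000.0)


def protocol_to_yaml(p: Protocol, path) -> None:
    payload = {
        "window_ms": p.window_ms, "dt_out": p.dt_out,
        "conditions": [_condition_to_dict(c) for c in p.conditions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def protocol_from_yaml(path) -> Protocol:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return Protocol(
        tuple(_condition_from_dict(d) for d in payload["conditions"]),
        window_ms=float(payload.get("window_ms", 5000.0)),
        dt_out=float(payload.get("dt_out", 0.1)))
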