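"""Fluorescence-recording ingestion and preprocessing.

Plate-imager recordings of voltage- and calcium-sensitive dyes arrive as
time/intensity tables (typically 125 samples per second).  Before they can
drive calibration they are (1) detrended by subtracting a moving-minimum
(grayscale erosion) baseline whose window exceeds one beat, (2) median
filtered, (3) resampled onto the pipeline grid, and (4) min-max normalized
— normalization is the sole fluorescence surrogate, there is no optical
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import grey_erosion
from scipy.signal import find_peaks, medfilt

from .calibration import CalibrationEnsemble, GAConfig, calibrate_ensemble, fitness
from .protocol import Condition, Protocol, TraceSet, normalize_traces, run_protocol
from .simulation import derive_initial_state
from .types import Trace

__all__ = ["RawRecording", "PreprocessConfig", "read_recording",
           "preprocess", "merge_channels", "run_invitro_calibration"]

CHANNELS = ("voltage-dye", "calcium-dye")


@dataclass(frozen=True)
class RawRecording:
    """One optical channel of one acquisition."""

    time_s: np.ndarray
    intensity: np.ndarray
    channel: str = "voltage-dye"
    sample_rate_hz: float = 125.0
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.intensity, dtype=float)
        if len(t) != len(x):
            raise ValueError("time and intensity must have equal length")
        if len(t) == 0:
            raise ValueError("no samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", x)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def read_recording(path, schema: dict | None = None,
                   channel: str = "voltage-dye",
                   condition: str = "") -> RawRecording:
    """Parse a delimited text recording.

    ``schema`` maps logical to file column names, e.g.
    ``{"time": "t", "value": "F"}``; defaults expect ``time_s`` and
    ``intensity``.  Parse problems raise errors naming the offending
    line numbers.
    """
    schema = {"time": "time_s", "value": "intensity", **(schema or {})}
    df = pd.read_csv(path)
    for key in ("time", "value"):
        if schema[key] not in df.columns:
            raise ValueError(
                f"{path}: missing column {schema[key]!r} "
                f"(found {list(df.columns)})")
    if len(df) == 0:
        raise ValueError(f"{path}: no samples")
    sub = df[[schema["time"], schema["value"]]].apply(
        pd.to_numeric, errors="coerce")
    bad = np.where(sub.isna().any(axis=1))[0]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])   # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric rows at lines {lines}")
    t = sub[schema["time"]].to_numpy()
    rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 and t[-1] > t[0] else 125.0
    return RawRecording(t, sub[schema["value"]].to_numpy(), channel=channel,
                        sample_rate_hz=rate, condition=condition)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing settings (package choices, not instrument facts)."""

    erosion_window_s: float | None = None   # None: 1.5 x median beat interval
    median_window: int = 5                  # samples at the native rate
    target_dt_ms: float = 0.1               # pipeline grid ("fine")
    compare_grid: str = "fine"              # fine | native


def _estimate_beat_interval_s(t: np.ndarray, x: np.ndarray) -> float:
    """Median peak-to-peak interval, for sizing the erosion window."""
    rng = x.max() - x.min()
    if rng <= 0:
        raise ValueError("constant signal (non-beating sample)")
    dt = np.median(np.diff(t))
    peaks, _ = find_peaks(x, prominence=0.3 * rng,
                          distance=max(1, int(0.25 / dt)))
    if len(peaks) < 2:
        return max(1.0, 0.25 * (t[-1] - t[0]))
    return float(np.median(np.diff(t[peaks])))


def preprocess(r: RawRecording, cfg: PreprocessConfig = PreprocessConfig()
               ) -> Trace:
    """Run the fixed pipeline: erode -> median filter -> resample -> normalize.

    Returns a single-channel Trace: the processed series occupies the V or
    Ca slot according to the recording's dye channel; the other slot is
    NaN.  Use :func:`merge_channels` to pair voltage and calcium recordings
    into a calibration-ready Trace.
    """
    if r.duration_s < 2.0:
        raise ValueError("need at least 2 s of data")
    t = r.time_s
    x = r.intensity.astype(float)

    # 1. baseline drift estimation by moving minimum; the window must span
    #    more than one beat so it tracks drift, not the transients
    win_s = cfg.erosion_window_s or 1.5 * _estimate_beat_interval_s(t, x)
    dt = float(np.median(np.diff(t)))
    win = max(3, int(round(win_s / dt)) | 1)
    baseline = grey_erosion(x, size=win, mode="nearest")
    x = x - baseline

    # 2. impulse-noise removal
    mw = max(1, cfg.median_window | 1)
    x = medfilt(x, kernel_size=mw)

    # 3. resample onto a uniform grid
    t_ms = (t - t[0]) * 1000.0
    if cfg.compare_grid == "fine":
        dt_ms = cfg.target_dt_ms
    else:
        dt_ms = dt * 1000.0
    n = int(np.floor(t_ms[-1] / dt_ms)) + 1
    grid = np.arange(n) * dt_ms
    x = np.interp(grid, t_ms, x)

    # 4. 0-1 normalization
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise ValueError("constant signal after preprocessing "
                         "(non-beating sample)")
    x = (x - lo) / (hi - lo)

    nan = np.full_like(x, np.nan)
    if r.channel == "voltage-dye":
        return Trace(grid, x, nan, normalized=True,
                     meta={"condition": r.condition, "channel": r.channel})
    return Trace(grid, nan, x, normalized=True,
                 meta={"condition": r.condition, "channel": r.channel})


def merge_channels(voltage: Trace, calcium: Trace) -> Trace:
    """Pair preprocessed voltage and calcium channels on a common grid."""
    n = min(len(voltage.t), len(calcium.t))
    if abs(voltage.dt - calcium.dt) > 1e-9:
        raise ValueError("channel grids differ; resample first")
    return Trace(voltage.t[:n], voltage.V[:n], calcium.Ca[:n],
                 normalized=True, meta={**calcium.meta, **voltage.meta})


def run_invitro_calibration(
    recordings: dict[str, dict[str, RawRecording]],
    protocol_map: dict[str, Condition],
    holdout: str,
    cfg: PreprocessConfig = PreprocessConfig(),
    ga_cfg: GAConfig = GAConfig(),
    n_runs: int = 10,
    window_ms: float | None = None,
) -> tuple[CalibrationEnsemble, dict]:
    """Calibrate to all non-held-out conditions and predict the hold-out.

    ``recordings``: condition label -> {"voltage-dye": rec, "calcium-dye": rec}.
    ``protocol_map`` supplies the simulation condition for every label.
    Returns the calibration ensemble and a validation report with exactly
    one hold-out entry (its prediction scores across the ensemble).
    """
    fit_labels = [lab for lab in protocol_map if lab != holdout]
    if holdout not in protocol_map:
        raise ValueError(f"hold-out condition {holdout!r} not in protocol map")
    if holdout in fit_labels:
        raise ValueError("hold-out condition present in the calibration set")

    def target_trace(lab: str) -> Trace:
        chans = recordings.get(lab)
        if chans is None:
            raise ValueError(f"no recordings for condition {lab!r}")
        for ch in CHANNELS:
            if ch not in chans:
                raise ValueError(f"missing {ch} recording for condition {lab!r}")
        return merge_channels(preprocess(chans["voltage-dye"], cfg),
                              preprocess(chans["calcium-dye"], cfg))

    traces = [target_trace(lab) for lab in fit_labels]
    win = window_ms if window_ms is not None else min(
        tr.duration for tr in traces)
    dt_nominal = (cfg.target_dt_ms if cfg.compare_grid == "fine"
                  else traces[0].dt)
    proto = Protocol(tuple(protocol_map[lab] for lab in fit_labels),
                     window_ms=win, dt_out=dt_nominal)

    def window_on_grid(tr: Trace) -> Trace:
        # trailing window interpolated onto the exact simulation grid, so
        # sample counts match the simulated candidates by construction
        n = int(round(win / dt_nominal)) + 1
        grid = np.arange(n) * dt_nominal
        t0 = tr.t[-1] - win
        return Trace(grid, np.interp(grid + t0, tr.t, tr.V),
                     np.interp(grid + t0, tr.t, tr.Ca), normalized=True,
                     meta=dict(tr.meta))

    target = TraceSet([window_on_grid(tr) for tr in traces],
                      protocol=proto, normalized=True)

    ens = calibrate_ensemble(target, proto, ga_cfg, n_runs=n_runs)

    x0 = derive_initial_state()
    hold_trace = window_on_grid(target_trace(holdout))
    hold_proto = Protocol((protocol_map[holdout],), window_ms=win,
                          dt_out=dt_nominal)
    hold_target = TraceSet([hold_trace], protocol=hold_proto, normalized=True)
    mses = []
    for run in ens.runs:
        pred = run_protocol(run.best, hold_proto, x0)
        if pred.failed:
            mses.append(float("nan"))
            continue
        pred = normalize_traces(pred)
        mses.append(fitness(pred, hold_target, alignment=ga_cfg.alignment))
    report = {
        "holdout": [{
            "condition": holdout,
            "prediction_mse": mses,
            "median_prediction_mse": float(np.nanmedian(mses)) if mses else None,
        }],
        "fit_conditions": fit_labels,
        "n_runs": n_runs,
    }
    return ens, report
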