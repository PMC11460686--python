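"""AP/CaT feature extraction and arrhythmia-dynamics classification.

Beats are located at threshold crossings of the smoothed time derivative of
the voltage (or normalized fluorescence) signal, with a refractory lockout.
Duration-type features (APD50/APD90, inter-beat intervals) are defined on
fractions of the beat amplitude, so they are identical on a raw trace and
its min-max-normalized copy; amplitude-type features scale with the signal.

The arrhythmia label set covers the dynamics relevant to I_Kr-block
susceptibility in single cells: afterdepolarizations, alternans, beating
cessation, tachycardia, and an "irregular" catch-all (the single-cell
surrogate for torsadogenic dynamics).  Detection thresholds are package
choices, collected in :class:`ArrhythmiaThresholds` and overridable from
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Trace

__all__ = [
    "BeatTable", "detect_beats", "apd", "amplitudes",
    "ArrhythmiaThresholds", "classify_arrhythmia", "ARRHYTHMIA_LABELS",
]

#: Columns of a beat table.
BEAT_COLUMNS = (
    "upstroke_ms", "peak_ms", "peak_value", "diastolic_value", "amplitude",
    "apd50_ms", "apd90_ms", "ca_peak", "ca_diastolic", "ca_amplitude",
)

BeatTable = pd.DataFrame

ARRHYTHMIA_LABELS = (
    "none", "afterdepolarization", "alternans", "cessation", "tachycardia",
    "irregular",
)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _upstroke_indices(t: np.ndarray, v: np.ndarray,
                      rel_threshold: float = 0.10,
                      lockout_ms: float = 200.0) -> np.ndarray:
    """Indices where smoothed dV/dt crosses ``rel_threshold`` of its maximum."""
    dt = t[1] - t[0]
    width = max(3, int(round(1.0 / dt)) | 1)     # ~1 ms smoothing, odd
    vs = _smooth(v, width)
    dv = np.gradient(vs, dt)
    dv_max = dv.max() if len(dv) else 0.0
    amp = vs.max() - vs.min()
    # a beating signal must show both slope and excursion well above noise
    if dv_max <= 0 or amp <= 0 or dv_max * dt < 1e-3 * amp:
        return np.array([], dtype=int)
    thr = rel_threshold * dv_max
    above = dv >= thr
    crossings = np.where(~above[:-1] & above[1:])[0] + 1
    if above[0]:
        # an upstroke already in progress at the window edge is still a beat
        crossings = np.concatenate(([0], crossings))
    lockout = int(round(lockout_ms / dt))
    picked: list[int] = []
    last = -lockout - 1
    for i in crossings:
        if i - last > lockout:
            picked.append(i)
            last = i
    return np.asarray(picked, dtype=int)


def apd(t: np.ndarray, v: np.ndarray, i_up: int, i_end: int,
        diastolic: float, fraction: float) -> float:
    """Action-potential duration at a repolarization fraction.

    Time from the upstroke to the point where the signal has repolarized
    ``fraction`` of the beat amplitude (APD90: fraction = 0.90), linearly
    interpolated between samples.  Returns NaN for a non-repolarizing beat.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    seg = v[i_up:i_end]
    if len(seg) < 2:
        return np.nan
    i_peak = int(np.argmax(seg))
    peak = seg[i_peak]
    level = peak - fraction * (peak - diastolic)
    after = seg[i_peak:]
    below = np.where(after <= level)[0]
    if len(below) == 0:
        return np.nan
    k = below[0]
    if k == 0:
        return t[i_up + i_peak] - t[i_up]
    # linear interpolation between samples k-1 and k
    v1, v2 = after[k - 1], after[k]
    frac = (v1 - level) / (v1 - v2) if v2 != v1 else 0.0
    t_cross = t[i_up + i_peak + k - 1] + frac * (t[1] - t[0])
    return float(t_cross - t[i_up])


def detect_beats(trace: Trace, rel_threshold: float = 0.10,
                 lockout_ms: float = 200.0) -> BeatTable:
    """Locate beats and tabulate per-beat features.

    Works on raw (mV) and normalized signals alike because the derivative
    threshold is relative.  Returns an empty table for flat traces.
    """
    t, v = trace.t, trace.V
    if len(t) < 3 or trace.failed:
        return pd.DataFrame(columns=list(BEAT_COLUMNS))
    ups = _upstroke_indices(t, v, rel_threshold, lockout_ms)
    rows = []
    for b, i_up in enumerate(ups):
        i_end = ups[b + 1] if b + 1 < len(ups) else len(v)
        i_prev = ups[b - 1] if b > 0 else 0
        dia = float(np.min(v[i_prev:i_up + 1])) if i_up > i_prev else float(v[i_up])
        seg = v[i_up:i_end]
        i_peak = i_up + int(np.argmax(seg))
        peak = float(v[i_peak])
        ca_seg = trace.Ca[i_up:i_end]
        ca_dia = float(np.min(trace.Ca[i_prev:i_up + 1])) if i_up > i_prev \
            else float(trace.Ca[i_up])
        ca_peak = float(np.max(ca_seg)) if len(ca_seg) else np.nan
        rows.append({
            "upstroke_ms": float(t[i_up]),
            "peak_ms": float(t[i_peak]),
            "peak_value": peak,
            "diastolic_value": dia,
            "amplitude": peak - dia,
            "apd50_ms": apd(t, v, i_up, i_end, dia, 0.50),
            "apd90_ms": apd(t, v, i_up, i_end, dia, 0.90),
            "ca_peak": ca_peak,
            "ca_diastolic": ca_dia,
            "ca_amplitude": ca_peak - ca_dia,
        })
    return pd.DataFrame(rows, columns=list(BEAT_COLUMNS))


def amplitudes(beat: pd.Series) -> tuple[float, float]:
    """(AP amplitude, CaT amplitude) of one beat-table row."""
    return float(beat["amplitude"]), float(beat["ca_amplitude"])


@dataclass(frozen=True)
class ArrhythmiaThresholds:
    """Detection thresholds for the arrhythmia classifier (package choices)."""

    cessation_min_beats: int = 2
    cessation_amp_fraction: float = 0.10   # of baseline amplitude
    ead_fraction: float = 0.05             # re-depolarization vs beat amplitude
    ead_decline_fraction: float = 0.02     # bump must decline by this much
    alternans_beats: int = 4
    alternans_fraction: float = 0.05       # APD90 excursion vs mean APD90
    tachycardia_hz: float = 2.0
    tachycardia_rate_factor: float = 2.0
    irregular_cv: float = 0.2


def _has_afterdepolarization(trace: Trace, beats: BeatTable,
                             thr: ArrhythmiaThresholds) -> bool:
    """Secondary depolarization bump between a beat's peak and the next
    upstroke.  A bump must rise and then fall again, so the smooth diastolic
    depolarization of a spontaneously beating cell does not count."""
    t, v = trace.t, trace.V
    dt = t[1] - t[0]
    width = max(3, int(round(2.0 / dt)) | 1)
    vs = _smooth(v, width)
    for b in range(len(beats)):
        i_peak = int(round((beats.iloc[b]["peak_ms"] - t[0]) / dt))
        i_end = int(round((beats.iloc[b + 1]["upstroke_ms"] - t[0]) / dt)) \
            if b + 1 < len(beats) else len(vs)
        amp = beats.iloc[b]["amplitude"]
        peak = beats.iloc[b]["peak_value"]
        seg = vs[i_peak:i_end]
        if len(seg) < 3 or amp <= 0:
            continue
        # arm only once repolarization has begun, so the peak itself (and
        # any smoothing transient around it) cannot register as a bump
        armed = False
        run_min = peak
        bump = 0.0
        for x in seg[1:]:
            if not armed:
                if x <= peak - 0.05 * amp:
                    armed = True
                    run_min = x
                continue
            if x < run_min:
                run_min = x
            rise = x - run_min
            if rise > bump:
                bump = rise
                bump_val = x
            elif bump >= thr.ead_fraction * amp and \
                    bump_val - x >= thr.ead_decline_fraction * amp:
                return True
    return False


def _has_alternans(beats: BeatTable, thr: ArrhythmiaThresholds) -> bool:
    apd90 = beats["apd90_ms"].to_numpy(dtype=float)
    apd90 = apd90[np.isfinite(apd90)]
    if len(apd90) < thr.alternans_beats:
        return False
    mean = float(np.mean(apd90))
    if mean <= 0:
        return False
    diffs = np.diff(apd90)
    need = thr.alternans_beats - 1      # alternating differences in a row
    run = 0
    for i, d in enumerate(diffs):
        big = abs(d) > thr.alternans_fraction * mean
        alternating = i == 0 or run == 0 or np.sign(d) == -np.sign(diffs[i - 1])
        if big and alternating:
            run += 1
            if run >= need:
                return True
        else:
            run = 1 if big else 0
    return False


def classify_arrhythmia(trace: Trace, baseline_rate: float | None = None,
                        baseline_amplitude: float | None = None,
                        thresholds: ArrhythmiaThresholds | None = None) -> str:
    """Label the steady-state dynamics of a trace.

    Priority order: cessation > afterdepolarization > alternans >
    tachycardia > irregular > none.  A failed (diverged) simulation counts
    as cessation of organized beating.  The classifier is pure: the same
    trace and thresholds always give the same label.
    """
    thr = thresholds or ArrhythmiaThresholds()
    if trace.failed:
        return "cessation"
    beats = detect_beats(trace)
    if len(beats) < thr.cessation_min_beats:
        return "cessation"
    if baseline_amplitude is not None and \
            (beats["amplitude"] < thr.cessation_amp_fraction
             * baseline_amplitude).all():
        return "cessation"
    if _has_afterdepolarization(trace, beats, thr):
        return "afterdepolarization"
    if _has_alternans(beats, thr):
        return "alternans"
    ups = beats["upstroke_ms"].to_numpy(dtype=float)
    intervals = np.diff(ups)
    rate = 1000.0 * (len(ups) - 1) / (ups[-1] - ups[0]) if len(ups) > 1 else 0.0
    tachy_limit = thr.tachycardia_hz
    if baseline_rate is not None:
        tachy_limit = max(thr.tachycardia_hz,
                          thr.tachycardia_rate_factor * baseline_rate)
    if rate > tachy_limit:
        return "tachycardia"
    if len(intervals) >= 3 and \
            np.std(intervals, ddof=1) / np.mean(intervals) > thr.irregular_cv:
        return "irregular"
    return "none"
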