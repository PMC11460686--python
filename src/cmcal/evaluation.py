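"""Scoring of calibrations, block-response prediction, arrhythmia
threshold scanning, and regression-based parameter sensitivity.

Calibration quality has two facets: per-parameter *error*
``|log2(fitted / true)|`` against the generator's ground truth, and
per-parameter *spread*, the sample standard deviation of
``log2(fitted / true)`` across repeated GA runs (a measure of how
consistently the data constrain that parameter).

Arrhythmia susceptibility is summarized as the I_Kr block tolerance
threshold: the lowest blocked fraction of the rapid delayed rectifier
current that induces arrhythmic dynamics in a given cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calibration import CalibrationEnsemble, fitness
from .features import ArrhythmiaThresholds, classify_arrhythmia, detect_beats
from .protocol import Protocol, TraceSet, baseline_condition, run_protocol
from .simulation import derive_initial_state
from .types import BlockMap, CONDUCTANCE_NAMES, ConductanceSet

__all__ = [
    "calibration_error", "calibration_spread", "predict_response",
    "prediction_scores", "ikr_block_threshold", "ThresholdResult",
    "sensitivity_regression", "SensitivityResult",
]


def calibration_error(fitted: ConductanceSet,
                      truth: ConductanceSet) -> pd.Series:
    """Per-parameter |log2(fitted/true)|; index = parameter names.

    The mean over the 16 parameters is the headline calibration error.
    """
    f = fitted.as_array()
    t = truth.as_array()
    if np.any(f <= 0) or np.any(t <= 0):
        raise ValueError("multipliers must be strictly positive")
    return pd.Series(np.abs(np.log2(f / t)), index=CONDUCTANCE_NAMES)


def calibration_spread(ensemble: CalibrationEnsemble,
                       truth: ConductanceSet) -> pd.Series:
    """Sample SD (ddof=1) across runs of log2(fitted/true), per parameter."""
    if len(ensemble) < 2:
        raise ValueError("spread is undefined for fewer than 2 runs")
    t = truth.as_array()
    logs = np.array([np.log2(r.best.as_array() / t) for r in ensemble.runs])
    return pd.Series(np.std(logs, axis=0, ddof=1), index=CONDUCTANCE_NAMES)


def predict_response(fitted: ConductanceSet,
                     perturbation: BlockMap | dict | None = None,
                     protocol: Protocol | None = None,
                     x0: np.ndarray | None = None) -> TraceSet:
    """Simulate the fitted model under an unseen perturbation.

    Default: 30% I_Kr block under the physiological baseline condition.
    """
    perturbation = BlockMap(perturbation if perturbation is not None
                            else {"I_Kr": 0.30})
    if protocol is None:
        protocol = Protocol((baseline_condition(),), window_ms=5_000.0,
                            dt_out=0.1)
    from dataclasses import replace
    conds = tuple(
        replace(c, blocks=BlockMap({**c.blocks, **perturbation}))
        for c in protocol.conditions)
    blocked = Protocol(conds, window_ms=protocol.window_ms,
                       dt_out=protocol.dt_out)
    x0 = derive_initial_state() if x0 is None else x0
    return run_protocol(fitted, blocked, x0)


def _apd90_over_amplitude(ts: TraceSet) -> float:
    """Median APD90 normalized to AP amplitude over a TraceSet's beats."""
    vals = []
    for tr in ts.traces:
        beats = detect_beats(tr)
        if len(beats) == 0:
            continue
        apd = beats["apd90_ms"].to_numpy(dtype=float)
        amp = beats["amplitude"].to_numpy(dtype=float)
        ok = np.isfinite(apd) & (amp > 0)
        vals.extend((apd[ok] / amp[ok]).tolist())
    return float(np.median(vals)) if vals else np.nan


def prediction_scores(predicted: TraceSet, truth: TraceSet,
                      predicted_baseline: TraceSet | None = None,
                      truth_baseline: TraceSet | None = None,
                      alignment: str = "per-beat") -> dict[str, float]:
    """Score a predicted block response against the ground-truth response.

    Returns:
      * ``trace_mse`` — beat-aligned pointwise MSE (same definition as the
        calibration fitness);
      * ``apd90_pct_error`` — percent error of the amplitude-normalized
        APD90 under the perturbation;
      * ``delta_apd90_pct_error`` — percent error of the change in
        amplitude-normalized APD90 (perturbed minus baseline); requires the
        baseline TraceSets.
    Missing beats yield NaN scores rather than exceptions.
    """
    scores: dict[str, float] = {}
    try:
        scores["trace_mse"] = fitness(predicted, truth, alignment=alignment)
    except ValueError:
        scores["trace_mse"] = np.nan
    a_pred = _apd90_over_amplitude(predicted)
    a_true = _apd90_over_amplitude(truth)
    scores["apd90_pct_error"] = (
        100.0 * abs(a_pred - a_true) / a_true
        if np.isfinite(a_pred) and np.isfinite(a_true) and a_true != 0
        else np.nan)
    if predicted_baseline is not None and truth_baseline is not None:
        d_pred = a_pred - _apd90_over_amplitude(predicted_baseline)
        d_true = a_true - _apd90_over_amplitude(truth_baseline)
        scores["delta_apd90_pct_error"] = (
            100.0 * abs(d_pred - d_true) / abs(d_true)
            if np.isfinite(d_pred) and np.isfinite(d_true) and d_true != 0
            else np.nan)
    return scores


@dataclass(frozen=True)
class ThresholdResult:
    """Lowest I_Kr block fraction (in %) inducing arrhythmic dynamics."""

    threshold_pct: float | None    # None = tolerant up to 100%
    label: str | None              # classification that triggered it
    step_pct: float
    labels_by_level: dict[float, str] = field(default_factory=dict)

    @property
    def tolerant(self) -> bool:
        return self.threshold_pct is None


def ikr_block_threshold(
    c: ConductanceSet,
    step_pct: float = 1.0,
    equil_ms: float = 300_000.0,
    window_ms: float = 30_000.0,
    baseline_rate: float | None = None,
    thresholds: ArrhythmiaThresholds | None = None,
    x0: np.ndarray | None = None,
    exhaustive: bool = False,
    dt_out: float = 1.0,
    level_classifier=None,
) -> ThresholdResult:
    """Scan I_Kr block levels ascending and return the first arrhythmic one.

    Each level is simulated independently from the cell's baseline state
    (``equil_ms`` of pre-equilibration, classification on the trailing
    ``window_ms``).  With ``exhaustive=True`` every level is evaluated and
    the minimum arrhythmic level returned — by construction identical to
    the ascending scan's answer, at brute-force cost.

    ``level_classifier`` (block %, -> label) replaces the simulation-based
    per-level evaluation; it exists for scan-logic verification.
    """
    if step_pct <= 0 or step_pct > 100:
        raise ValueError("step_pct must be in (0, 100]")
    if level_classifier is None:
        x0 = derive_initial_state() if x0 is None else x0
        if baseline_rate is None:
            from .dataset import spontaneous_rate
            p0 = Protocol((baseline_condition(equil_ms),),
                          window_ms=window_ms, dt_out=dt_out)
            ts0 = run_protocol(c, p0, x0)
            baseline_rate = (None if ts0.failed
                             else spontaneous_rate(ts0.traces[0]))

        def level_classifier(lv: float) -> str:
            from dataclasses import replace
            cond = replace(baseline_condition(equil_ms),
                           blocks=BlockMap({"I_Kr": lv / 100.0}))
            p = Protocol((cond,), window_ms=window_ms, dt_out=dt_out)
            ts = run_protocol(c, p, x0)
            return classify_arrhythmia(ts.traces[0],
                                       baseline_rate=baseline_rate,
                                       thresholds=thresholds)

    levels = np.arange(step_pct, 100.0 + step_pct / 2, step_pct)
    labels: dict[float, str] = {}
    first: tuple[float, str] | None = None
    for lv in levels:
        label = level_classifier(float(lv))
        labels[float(lv)] = label
        if label != "none" and first is None:
            first = (float(lv), label)
            if not exhaustive:
                break
    if exhaustive and labels:
        arr = sorted(lv for lv, lab in labels.items() if lab != "none")
        first = (arr[0], labels[arr[0]]) if arr else None
    if first is None:
        return ThresholdResult(None, None, step_pct, labels)
    return ThresholdResult(first[0], first[1], step_pct, labels)


@dataclass
class SensitivityResult:
    """OLS coefficients of z-scored outputs on z-scored log2 multipliers."""

    coefficients: pd.DataFrame        # rows: parameters, cols: outputs
    r_squared: dict[str, float]

    def top_parameters(self, output: str, k: int = 4) -> list[str]:
        s = self.coefficients[output].abs().sort_values(ascending=False)
        return list(s.index[:k])

    def bottom_parameters(self, output: str, k: int = 4) -> list[str]:
        s = self.coefficients[output].abs().sort_values(ascending=True)
        return list(s.index[:k])


def sensitivity_regression(population: list[ConductanceSet],
                           outputs: pd.DataFrame,
                           log_transform_outputs: bool = True
                           ) -> SensitivityResult:
    """Multivariable linear regression of phenotypes on log-conductances.

    ``outputs``: one row per cell, one column per phenotype (e.g. APD90,
    CaT amplitude, I_Kr block threshold).  Strictly positive outputs are
    log-transformed; predictors and responses are z-scored, so coefficient
    magnitudes are comparable across outputs and parameters.
    """
    x = np.log2(np.array([c.as_array() for c in population]))
    if len(population) != len(outputs):
        raise ValueError("population and outputs must have equal length")
    if len(population) <= x.shape[1] + 1:
        raise ValueError("population too small for a 16-parameter regression")
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    coefs = {}
    r2 = {}
    for col in outputs.columns:
        y = outputs[col].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if keep.sum() <= x.shape[1] + 1:
            raise ValueError(f"too few finite values for output {col!r}")
        yk = y[keep]
        if log_transform_outputs and np.all(yk > 0):
            yk = np.log(yk)
        ys = (yk - yk.mean()) / yk.std(ddof=1)
        model = sm.OLS(ys, sm.add_constant(xs[keep]))
        try:
            res = model.fit()
        except np.linalg.LinAlgError as exc:   # pragma: no cover
            raise ValueError("rank-deficient design matrix") from exc
        if np.linalg.matrix_rank(xs[keep]) < x.shape[1]:
            raise ValueError("rank-deficient design matrix")
        coefs[col] = res.params[1:]
        r2[col] = float(res.rsquared)
    df = pd.DataFrame(coefs, index=CONDUCTANCE_NAMES)
    return SensitivityResult(df, r2)
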