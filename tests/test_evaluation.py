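"""Calibration metrics, block-response scoring, threshold scanning and
regression sensitivity."""

import numpy as np
import pandas as pd
import pytest

from cmcal import ConductanceSet
from cmcal.calibration import CalibrationEnsemble, CalibrationRun, GAConfig
from cmcal.dataset import draw_multipliers
from cmcal.evaluation import (calibration_error, calibration_spread,
                              ikr_block_threshold, prediction_scores,
                              sensitivity_regression)
from cmcal.protocol import TraceSet
from cmcal.types import CONDUCTANCE_NAMES
from conftest import synthetic_ap_train


def _fake_run(multiplier_set):
    cfg = GAConfig(population_size=4, generations=1)
    return CalibrationRun(best=multiplier_set, best_fitness=0.0,
                          history_best=[1.0, 0.5], history_mean=[2.0, 1.0],
                          seed=0, config=cfg)


class TestCalibrationError:
    def test_perfect_fit_is_zero(self):
        c = ConductanceSet()
        assert calibration_error(c, c).sum() == 0.0

    @pytest.mark.parametrize("factor", [2.0, 0.5])
    def test_twofold_error_is_one(self, factor):
        truth = ConductanceSet()
        fitted = truth.with_(g_Kr=factor)
        err = calibration_error(fitted, truth)
        assert err["g_Kr"] == pytest.approx(1.0)
        assert err.drop("g_Kr").sum() == 0.0

    def test_mean_over_16_parameters(self):
        truth = ConductanceSet()
        fitted = ConductanceSet((2.0,) * 16)
        assert calibration_error(fitted, truth).mean() == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            calibration_error(ConductanceSet((0.0,) + (1.0,) * 15),
                              ConductanceSet())


class TestCalibrationSpread:
    def test_identical_runs_have_zero_spread(self):
        ens = CalibrationEnsemble([_fake_run(ConductanceSet())
                                   for _ in range(3)])
        assert calibration_spread(ens, ConductanceSet()).sum() == 0.0

    def test_sample_sd_convention(self):
        # runs at 2x and 0.5x truth: log2 ratios {+1, -1}, sample SD sqrt(2)
        truth = ConductanceSet()
        ens = CalibrationEnsemble([_fake_run(truth.with_(g_Kr=2.0)),
                                   _fake_run(truth.with_(g_Kr=0.5))])
        spread = calibration_spread(ens, truth)
        assert spread["g_Kr"] == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_invariant_to_common_rescaling(self):
        truth = ConductanceSet()
        fits = [truth.with_(g_Kr=2.0), truth.with_(g_Kr=0.7)]
        ens1 = CalibrationEnsemble([_fake_run(f) for f in fits])
        k = 3.7
        truth_k = ConductanceSet(tuple(v * k for v in truth.values))
        fits_k = [ConductanceSet(tuple(v * k for v in f.values)) for f in fits]
        ens2 = CalibrationEnsemble([_fake_run(f) for f in fits_k])
        assert np.allclose(calibration_spread(ens1, truth),
                           calibration_spread(ens2, truth_k))


class TestPredictionScores:
    def test_identical_prediction_scores_zero(self):
        ts = TraceSet([synthetic_ap_train()])
        s = prediction_scores(ts, ts.copy())
        assert s["trace_mse"] == 0.0
        assert s["apd90_pct_error"] == 0.0

    def test_apd_ratio_percent_error(self):
        # 10% longer APD at equal amplitude -> 10% error
        truth = TraceSet([synthetic_ap_train(apd=300.0, n_beats=3,
                                             period_ms=1500.0)])
        pred = TraceSet([synthetic_ap_train(apd=330.0, n_beats=3,
                                            period_ms=1500.0)])
        s = prediction_scores(pred, truth)
        assert s["apd90_pct_error"] == pytest.approx(10.0, abs=1.0)

    def test_mse_matches_fitness_definition(self):
        from cmcal.calibration import fitness
        a = TraceSet([synthetic_ap_train()])
        b = TraceSet([synthetic_ap_train(apd=320.0)])
        s = prediction_scores(a, b)
        assert s["trace_mse"] == fitness(a, b)

    def test_missing_beats_give_nan(self):
        t = synthetic_ap_train()
        flat = t.copy()
        flat.V = np.full_like(flat.V, -70.0)
        s = prediction_scores(TraceSet([flat]), TraceSet([t]))
        assert np.isnan(s["apd90_pct_error"])


class TestThresholdScan:
    def test_first_arrhythmic_level_contract(self):
        clf = lambda lv: "afterdepolarization" if lv >= 37 else "none"
        res = ikr_block_threshold(ConductanceSet(), step_pct=1.0,
                                  level_classifier=clf)
        assert res.threshold_pct == 37.0
        assert res.label == "afterdepolarization"
        assert not res.tolerant

    def test_ascending_equals_exhaustive(self):
        rng = np.random.default_rng(4)
        cut = rng.integers(10, 90)
        clf = lambda lv: "alternans" if lv >= cut else "none"
        asc = ikr_block_threshold(ConductanceSet(), step_pct=1.0,
                                  level_classifier=clf)
        exh = ikr_block_threshold(ConductanceSet(), step_pct=1.0,
                                  level_classifier=clf, exhaustive=True)
        assert asc.threshold_pct == exh.threshold_pct == float(cut)
        assert len(exh.labels_by_level) == 100

    def test_tolerant_sentinel(self):
        res = ikr_block_threshold(ConductanceSet(), step_pct=5.0,
                                  level_classifier=lambda lv: "none")
        assert res.tolerant and res.threshold_pct is None

    def test_coarser_step_bounds_finer_result(self):
        clf = lambda lv: "cessation" if lv >= 43 else "none"
        fine = ikr_block_threshold(ConductanceSet(), step_pct=1.0,
                                   level_classifier=clf)
        coarse = ikr_block_threshold(ConductanceSet(), step_pct=5.0,
                                     level_classifier=clf)
        assert coarse.threshold_pct >= fine.threshold_pct
        assert coarse.threshold_pct - fine.threshold_pct < 5.0

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            ikr_block_threshold(ConductanceSet(), step_pct=0.0,
                                level_classifier=lambda lv: "none")


class TestSensitivityRegression:
    def test_recovers_planted_linear_coefficients(self):
        rng = np.random.default_rng(11)
        cells = draw_multipliers(400, spread=0.2, seed=11)
        x = np.log2([c.as_array() for c in cells])
        beta = np.zeros(16)
        beta[CONDUCTANCE_NAMES.index("g_Kr")] = -0.8
        beta[CONDUCTANCE_NAMES.index("g_CaL")] = 0.5
        y = x @ beta + rng.normal(0, 0.02, len(cells))
        res = sensitivity_regression(cells, pd.DataFrame({"out": y}),
                                     log_transform_outputs=False)
        coef = res.coefficients["out"]
        # z-scored coefficients preserve sign and relative magnitude
        assert coef["g_Kr"] < 0 < coef["g_CaL"]
        assert abs(coef["g_Kr"]) / abs(coef["g_CaL"]) == pytest.approx(
            0.8 / 0.5, rel=0.1)
        assert res.top_parameters("out", 2) == ["g_Kr", "g_CaL"]

    def test_independent_output_has_null_coefficient(self):
        rng = np.random.default_rng(3)
        cells = draw_multipliers(500, spread=0.2, seed=3)
        x = np.log2([c.as_array() for c in cells])
        y = 2.0 * x[:, CONDUCTANCE_NAMES.index("g_Na")] \
            + rng.normal(0, 0.05, len(cells))
        res = sensitivity_regression(cells, pd.DataFrame({"out": y}),
                                     log_transform_outputs=False)
        assert abs(res.coefficients["out"]["g_Kr"]) < 0.05

    def test_zscoring_makes_units_irrelevant(self):
        cells = draw_multipliers(300, spread=0.2, seed=5)
        x = np.log2([c.as_array() for c in cells])
        y = x @ np.linspace(-1, 1, 16)
        r1 = sensitivity_regression(cells, pd.DataFrame({"out": y}),
                                    log_transform_outputs=False)
        r2 = sensitivity_regression(cells, pd.DataFrame({"out": 1e3 * y}),
                                    log_transform_outputs=False)
        assert np.allclose(r1.coefficients, r2.coefficients)

    def test_undersized_population_rejected(self):
        cells = draw_multipliers(10, seed=0)
        with pytest.raises(ValueError):
            sensitivity_regression(cells,
                                   pd.DataFrame({"out": np.ones(10)}),
                                   log_transform_outputs=False)
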