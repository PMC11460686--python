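"""Fitness function contracts and genetic-algorithm behavior.

The GA tests run on deliberately small problems (short protocols, small
populations) — they check algorithmic properties, not recovery accuracy,
which has its own dedicated test.
"""

import numpy as np
import pytest

from cmcal import ConductanceSet, Trace
from cmcal.calibration import (GAConfig, SENTINEL_FITNESS, calibrate_ensemble,
                               fitness, ga_run)
from cmcal.protocol import (Protocol, TraceSet, baseline_condition,
                            normalize_traces, run_protocol)
from conftest import synthetic_ap_train


@pytest.fixture(scope="module")
def short_protocol():
    return Protocol((baseline_condition(10_000.0),), window_ms=4_000.0,
                    dt_out=1.0)


@pytest.fixture(scope="module")
def short_target(short_protocol, x0):
    truth = ConductanceSet().with_(g_Kr=1.3)
    ts = run_protocol(truth, short_protocol, x0)
    return normalize_traces(ts)


class TestFitness:
    def test_identical_tracesets_score_zero(self):
        ts = TraceSet([synthetic_ap_train()])
        assert fitness(ts, ts.copy()) == 0.0

    def test_constant_offset_contributes_c_squared(self):
        base = synthetic_ap_train()
        c = 3.0
        shifted = Trace(base.t, base.V + c, base.Ca)
        val = fitness(TraceSet([shifted]), TraceSet([base]))
        assert val == pytest.approx(c ** 2, rel=1e-6)

    def test_offset_per_segment_sums(self):
        base = synthetic_ap_train()
        c = 2.0
        cand = TraceSet([Trace(base.t, base.V + c, base.Ca),
                         Trace(base.t, base.V + c, base.Ca)])
        targ = TraceSet([base, base.copy()])
        assert fitness(cand, targ) == pytest.approx(2 * c ** 2, rel=1e-6)

    def test_nonbeating_candidate_gets_sentinel(self):
        base = synthetic_ap_train()
        flat = Trace(base.t, np.full_like(base.V, -70.0),
                     np.full_like(base.Ca, 1e-4))
        assert fitness(TraceSet([flat]), TraceSet([base])) == SENTINEL_FITNESS

    def test_failed_candidate_gets_sentinel(self):
        base = synthetic_ap_train()
        failed = base.copy()
        failed.failed = True
        assert fitness(TraceSet([failed]), TraceSet([base])) == SENTINEL_FITNESS

    def test_grid_mismatch_rejected(self):
        a = synthetic_ap_train(dt=1.0)
        b = synthetic_ap_train(dt=2.0)
        with pytest.raises(ValueError):
            fitness(TraceSet([a]), TraceSet([b]))

    def test_normalization_flag_mismatch_rejected(self):
        a = TraceSet([synthetic_ap_train()], normalized=True)
        b = TraceSet([synthetic_ap_train()], normalized=False)
        with pytest.raises(ValueError):
            fitness(a, b)

    def test_alignment_removes_phase_offset(self):
        # same waveform started 300 ms later should align to near-zero error
        a = synthetic_ap_train(lead_ms=100.0, n_beats=4)
        b = synthetic_ap_train(lead_ms=400.0, n_beats=4)
        n = min(len(a.t), len(b.t))
        ta = TraceSet([Trace(a.t[:n], a.V[:n], a.Ca[:n])])
        tb = TraceSet([Trace(b.t[:n], b.V[:n], b.Ca[:n])])
        aligned = fitness(ta, tb, alignment="first-upstroke")
        unaligned = fitness(ta, tb, alignment="none")
        assert aligned < 0.05 * unaligned


class TestGaRun:
    def test_best_fitness_non_increasing_and_reproducible(
            self, short_target, short_protocol, x0):
        cfg = GAConfig(population_size=6, generations=3,
                       free_parameters=("g_Kr", "g_CaL"), seed=123)
        run1 = ga_run(short_target, short_protocol, cfg, x0=x0)
        assert np.all(np.diff(run1.history_best) <= 1e-15)
        run2 = ga_run(short_target, short_protocol, cfg, x0=x0)
        assert run1.best == run2.best
        assert run1.history_best == run2.history_best

    def test_different_seeds_explore_differently(
            self, short_target, short_protocol, x0):
        cfg = GAConfig(population_size=6, generations=2,
                       free_parameters=("g_Kr", "g_CaL"), seed=1)
        cfg2 = GAConfig(population_size=6, generations=2,
                        free_parameters=("g_Kr", "g_CaL"), seed=2)
        r1 = ga_run(short_target, short_protocol, cfg, x0=x0)
        r2 = ga_run(short_target, short_protocol, cfg2, x0=x0)
        assert r1.best != r2.best

    def test_planted_target_closure(self, short_target, short_protocol, x0):
        truth = short_target.source
        cfg = GAConfig(population_size=6, generations=2,
                       free_parameters=("g_Kr", "g_CaL"), seed=9)
        run = ga_run(short_target, short_protocol, cfg, x0=x0,
                     seed_population=[truth])
        assert run.best_fitness == 0.0
        assert run.best["g_Kr"] == pytest.approx(truth["g_Kr"])

    def test_bounds_must_contain_baseline(self):
        with pytest.raises(ValueError):
            GAConfig(bounds_log2=(0.5, 2.0))


class TestEnsemble:
    def test_ensemble_runs_have_distinct_seeds(self, short_target,
                                               short_protocol, x0):
        cfg = GAConfig(population_size=4, generations=1,
                       free_parameters=("g_Kr",), seed=7)
        ens = calibrate_ensemble(short_target, short_protocol, cfg,
                                 n_runs=3, x0=x0)
        assert len(ens) == 3
        assert len({r.seed for r in ens.runs}) == 3
        assert len(ens.best_sets) == 3

    def test_summary_statistics_permutation_invariant(self, short_target,
                                                      short_protocol, x0):
        from cmcal.evaluation import calibration_spread
        from cmcal.calibration import CalibrationEnsemble
        cfg = GAConfig(population_size=4, generations=1,
                       free_parameters=("g_Kr",), seed=3)
        ens = calibrate_ensemble(short_target, short_protocol, cfg,
                                 n_runs=3, x0=x0)
        truth = short_target.source
        s1 = calibration_spread(ens, truth)
        shuffled = CalibrationEnsemble(list(reversed(ens.runs)))
        s2 = calibration_spread(shuffled, truth)
        assert np.allclose(s1, s2)

    def test_single_run_ensemble_rejected_for_spread(self, short_target,
                                                     short_protocol, x0):
        from cmcal.calibration import CalibrationEnsemble
        from cmcal.evaluation import calibration_spread
        cfg = GAConfig(population_size=4, generations=1,
                       free_parameters=("g_Kr",), seed=3)
        run = ga_run(short_target, short_protocol, cfg, x0=x0)
        with pytest.raises(ValueError):
            calibration_spread(CalibrationEnsemble([run]),
                               short_target.source)
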