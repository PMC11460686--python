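"""Protocol composition, windowing, resampling and normalization."""

import numpy as np
import pytest

from cmcal import ConductanceSet, Trace, simulate
from cmcal.protocol import (Condition, Protocol, TraceSet, baseline_condition,
                            condition_library, extract_window,
                            normalize_traces, optimized_protocol,
                            protocol_from_yaml, protocol_to_yaml,
                            resample_uniform, run_protocol)
from cmcal.types import ExtracellularMilieu


def make_trace(dur=1000.0, dt=1.0, f=lambda t: -70 + 10 * np.sin(t / 50)):
    t = np.arange(0.0, dur + dt / 2, dt)
    v = f(t)
    return Trace(t, v, np.abs(v) * 1e-5 + 1e-4)


class TestExtractWindow:
    def test_trailing_window_rezeroed(self):
        tr = make_trace(dur=300_000.0, dt=10.0)
        w = extract_window(tr, 5000.0)
        assert w.t[0] == 0.0
        assert w.duration == pytest.approx(5000.0)
        assert np.array_equal(w.V, tr.V[-len(w.t):])

    def test_full_window_is_whole_trace(self):
        tr = make_trace(dur=2000.0)
        w = extract_window(tr, tr.duration)
        assert len(w.t) == len(tr.t)

    def test_sample_count(self):
        tr = make_trace(dur=10_000.0, dt=0.1)
        w = extract_window(tr, 5000.0)
        assert len(w.t) == 50_001

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError):
            extract_window(make_trace(dur=1000.0), 5000.0)


class TestResample:
    def test_linear_signal_exact(self):
        tr = make_trace(dur=100.0, dt=1.0, f=lambda t: 2.0 * t)
        for dt in (0.3, 0.5, 2.0):
            rs = resample_uniform(tr, dt)
            assert np.allclose(rs.V, 2.0 * rs.t, atol=1e-12)

    def test_identity_on_own_grid(self):
        tr = make_trace(dur=100.0, dt=0.5)
        rs = resample_uniform(tr, 0.5)
        assert np.allclose(rs.V, tr.V)
        assert np.allclose(rs.t, tr.t)

    def test_interpolation_error_bound_for_sine(self):
        # linear interpolation error <= dt^2 * max|v''| / 8
        f_khz = 0.001  # 1 kHz in 1/ms
        omega = 2 * np.pi * f_khz
        t = np.arange(0.0, 2000.0, 1.0)
        tr = Trace(t, np.sin(omega * t), np.zeros_like(t))
        fine = resample_uniform(tr, 0.1)
        exact = np.sin(omega * fine.t)
        bound = 1.0 ** 2 * omega ** 2 / 8
        assert np.max(np.abs(fine.V - exact)) <= bound + 1e-12

    def test_nonmonotone_grid_rejected(self):
        tr = make_trace(dur=10.0)
        tr.t = tr.t.copy()
        tr.t[3] = tr.t[2]  # corrupt after construction
        with pytest.raises(ValueError):
            resample_uniform(tr, 0.5)


class TestNormalize:
    def test_exact_span_and_formula(self):
        tr = make_trace()
        tr.V = np.linspace(-75.0, 25.0, len(tr.t))
        ts = normalize_traces(TraceSet([tr]))
        v = ts.traces[0].V
        assert v.min() == 0.0 and v.max() == 1.0
        assert np.allclose(v, (tr.V + 75.0) / 100.0)
        assert ts.normalized and ts.traces[0].normalized

    def test_affine_invariance(self):
        tr = make_trace()
        scaled = Trace(tr.t, 3.0 * tr.V + 17.0, tr.Ca)
        n1 = normalize_traces(TraceSet([tr.copy()])).traces[0].V
        n2 = normalize_traces(TraceSet([scaled])).traces[0].V
        assert np.allclose(n1, n2)

    def test_idempotence(self):
        ts = normalize_traces(TraceSet([make_trace()]))
        again = normalize_traces(ts.copy())
        assert np.allclose(ts.traces[0].V, again.traces[0].V)

    def test_constant_segment_rejected(self):
        tr = make_trace(f=lambda t: np.full_like(t, -70.0))
        with pytest.raises(ValueError):
            normalize_traces(TraceSet([tr]))

    def test_global_mode_spans_unit_interval_jointly(self):
        t1 = make_trace(f=lambda t: -70 + 10 * np.sin(t / 40))
        t2 = make_trace(f=lambda t: -60 + 30 * np.sin(t / 40))
        ts = normalize_traces(TraceSet([t1, t2]), mode="global")
        all_v = np.concatenate([tr.V for tr in ts.traces])
        assert all_v.min() == 0.0 and all_v.max() == 1.0
        # the weaker segment must not span the full interval by itself
        assert ts.traces[0].V.max() < 1.0


class TestRunProtocol:
    def test_single_condition_equals_simulate_plus_window(self, x0):
        cond = baseline_condition(20_000.0)
        p = Protocol((cond,), window_ms=5_000.0, dt_out=1.0)
        ts = run_protocol(ConductanceSet(), p, x0)
        direct = simulate(ConductanceSet(), cond.milieu, cond.blocks, None,
                          duration_ms=20_000.0, x0=x0, dt_out=1.0,
                          record_start=15_000.0)
        assert np.array_equal(ts.traces[0].V, direct.V)
        assert np.array_equal(ts.traces[0].Ca, direct.Ca)

    def test_three_conditions_three_segments(self, x0):
        p = optimized_protocol(duration_ms=8_000.0, window_ms=3_000.0,
                               dt_out=1.0)
        ts = run_protocol(ConductanceSet(), p, x0)
        assert len(ts) == 3
        assert all(len(tr.V) == len(tr.Ca) == 3001 for tr in ts.traces)

    def test_carry_over_matches_manual_chaining(self, x0):
        conds = (baseline_condition(10_000.0),
                 Condition("low_ca", ExtracellularMilieu(Ca_o=1.0), None, {},
                           10_000.0))
        p = Protocol(conds, window_ms=4_000.0, dt_out=1.0)
        ts = run_protocol(ConductanceSet(), p, x0)
        first = simulate(ConductanceSet(), conds[0].milieu, {}, None,
                         duration_ms=10_000.0, x0=x0, dt_out=1.0,
                         record_start=6_000.0)
        second = simulate(ConductanceSet(), conds[1].milieu, {}, None,
                          duration_ms=10_000.0,
                          x0=first.meta["final_state"], dt_out=1.0,
                          record_start=6_000.0)
        assert np.array_equal(ts.traces[1].V, second.V)
        assert np.array_equal(ts.traces[1].meta["final_state"],
                              second.meta["final_state"])

    def test_consecutive_identical_conditions_superimpose(self, x0):
        # steady-state continuation: the two windows should align beat for
        # beat after a circular shift
        from cmcal.features import _upstroke_indices
        conds = (baseline_condition(60_000.0), baseline_condition(60_000.0))
        p = Protocol(conds, window_ms=5_000.0, dt_out=1.0)
        ts = run_protocol(ConductanceSet(), p, x0)
        v1, v2 = ts.traces[0].V, ts.traces[1].V
        grid = np.arange(len(v1), dtype=float)
        u1 = _upstroke_indices(grid, v1)[0]
        u2 = _upstroke_indices(grid, v2)[0]
        # linear shift, compare the overlapping span only
        a = v1[u1:]
        b = v2[u2:]
        n = min(len(a), len(b))
        amp = v1.max() - v1.min()
        assert n > 2000
        assert np.sqrt(np.mean((a[:n] - b[:n]) ** 2)) < 0.05 * amp

    def test_window_longer_than_condition_rejected(self):
        with pytest.raises(ValueError):
            Protocol((baseline_condition(1_000.0),), window_ms=5_000.0)


class TestLibraryAndYaml:
    def test_condition_library_has_19_conditions(self):
        lib = condition_library()
        assert len(lib) == 19
        assert "baseline" in lib
        assert lib["baseline"].stim is None
        assert lib["baseline"].milieu.Ca_o == 1.8

    def test_optimized_protocol_structure(self):
        p = optimized_protocol()
        assert len(p.conditions) == 3
        assert p.conditions[0].milieu.Ca_o == 1.0
        assert p.conditions[1].milieu.Ca_o == 1.8
        assert p.conditions[2].stim is not None
        assert p.conditions[2].blocks == {"I_CaL": 0.25}

    def test_yaml_round_trip(self, tmp_path):
        p = optimized_protocol(duration_ms=12_345.0, window_ms=2_000.0)
        path = tmp_path / "proto.yaml"
        protocol_to_yaml(p, path)
        q = protocol_from_yaml(path)
        assert len(q.conditions) == 3
        assert q.window_ms == 2_000.0
        for a, b in zip(p.conditions, q.conditions):
            assert a.milieu == b.milieu
            assert dict(a.blocks) == dict(b.blocks)
            assert a.duration_ms == b.duration_ms
            assert (a.stim is None) == (b.stim is None)
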