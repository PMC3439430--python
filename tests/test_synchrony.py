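"""Hilbert phases and Kuramoto order parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from glycosync import (
    CellTraceSet,
    PopulationConfig,
    instantaneous_phase,
    order_parameter_series,
    simulate_population,
    summarize_sync,
)
from glycosync.pipeline import analyze_traces
from glycosync.synchrony import PhaseSet, SyncSeries

DT = 2.0


def make_traces(values):
    values = np.atleast_2d(values)
    return CellTraceSet(np.arange(values.shape[1]) * DT, values)


def phase_set(angles):
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    t = np.arange(angles.shape[1]) * DT
    return PhaseSet(time_s=t, wrapped=angles, unwrapped=angles,
                    cell_ids=np.arange(angles.shape[0]),
                    undefined=np.zeros(angles.shape[0], bool))


class TestInstantaneousPhase:
    def test_sinusoid_phase_slope(self):
        t = np.arange(1024) * DT
        ps = instantaneous_phase(make_traces(np.sin(2 * np.pi * t / 40.0)))
        core = slice(50, -50)
        slope = np.gradient(ps.unwrapped[0], t)[core]
        assert slope.mean() == pytest.approx(2 * np.pi / 40.0, rel=0.01)
        assert np.allclose(slope, 2 * np.pi / 40.0, rtol=0.05)

    def test_quadrature_pair_offset(self):
        t = np.arange(1024) * DT
        arg = 2 * np.pi * t / 40.0
        ps = instantaneous_phase(make_traces(np.vstack([np.cos(arg), np.sin(arg)])))
        core = slice(50, -50)
        diff = ps.unwrapped[0, core] - ps.unwrapped[1, core]
        assert np.allclose(diff, np.pi / 2, atol=0.05)

    def test_slow_envelope_leaves_phase_slope(self):
        """Bedrosian condition: an AM tone with a slow envelope keeps its carrier slope."""
        t = np.arange(2048) * DT
        env = 1.0 + 0.5 * np.sin(2 * np.pi * t / 1000.0)
        ps = instantaneous_phase(make_traces(env * np.sin(2 * np.pi * t / 40.0)))
        core = slice(100, -100)
        slope = np.gradient(ps.unwrapped[0], t)[core].mean()
        assert slope == pytest.approx(2 * np.pi / 40.0, rel=0.02)

    def test_wrapped_range_and_consistency(self):
        t = np.arange(512) * DT
        ps = instantaneous_phase(make_traces(np.sin(2 * np.pi * t / 30.0)))
        assert ps.wrapped.min() > -np.pi and ps.wrapped.max() <= np.pi
        k = (ps.unwrapped - ps.wrapped) / (2 * np.pi)
        assert np.allclose(k, np.round(k), atol=1e-9)

    def test_zero_trace_flagged_not_fatal(self):
        t = np.arange(256) * DT
        values = np.vstack([np.sin(2 * np.pi * t / 40.0), np.zeros_like(t)])
        with pytest.warns(UserWarning, match="undefined"):
            ps = instantaneous_phase(make_traces(values))
        assert not ps.undefined[0] and ps.undefined[1]
        assert np.isnan(ps.wrapped[1]).all()
        assert np.isfinite(ps.wrapped[0]).all()


class TestOrderParameter:
    def test_identical_phases_give_exactly_one(self):
        angles = np.tile(np.sin(np.linspace(0, 9, 200)) * np.pi, (50, 1))
        series = order_parameter_series(phase_set(angles))
        # identity case: exact up to double-precision rounding of the phasor sum
        assert np.abs(series.order_parameter - 1.0).max() < 1e-12

    def test_antiphase_pair_cancels(self):
        series = order_parameter_series(phase_set([[0.0] * 10, [np.pi] * 10]))
        assert np.allclose(series.order_parameter, 0.0, atol=1e-12)

    def test_three_cell_complex_sum(self):
        # |e^0 + e^0 + e^{iπ}|/3 = 1/3
        series = order_parameter_series(phase_set([[0.0, 0.0], [0.0, 0.0], [np.pi, np.pi]]))
        assert np.allclose(series.order_parameter, 1.0 / 3.0)

    def test_global_phase_shift_invariance(self, rng):
        angles = rng.uniform(-np.pi, np.pi, size=(20, 50))
        k0 = order_parameter_series(phase_set(angles)).order_parameter
        k1 = order_parameter_series(phase_set(angles + 1.234)).order_parameter
        assert np.allclose(k0, k1, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                   min_side=2, max_side=12),
                      elements=st.floats(-50, 50)))
    def test_bounds_on_arbitrary_phases(self, angles):
        k = order_parameter_series(phase_set(angles)).order_parameter
        assert np.all(k >= 0.0) and np.all(k <= 1.0)

    def test_undefined_cells_excluded_and_counted(self):
        angles = np.array([[0.0, 0.0], [np.nan, 0.0]])
        series = order_parameter_series(phase_set(angles))
        assert series.n_cells_used.tolist() == [1, 2]
        assert series.order_parameter[0] == 1.0

    def test_no_usable_cells_masked(self):
        series = order_parameter_series(phase_set([[np.nan, 0.0]]))
        assert np.isnan(series.order_parameter[0])
        assert series.order_parameter[1] == 1.0

    def test_edge_exclusion_masks_ends(self):
        angles = np.zeros((3, 100))
        series = order_parameter_series(phase_set(angles), edge_exclude_s=20.0)
        assert np.isnan(series.order_parameter[:10]).all()
        assert np.isnan(series.order_parameter[-10:]).all()
        assert np.all(series.order_parameter[10:-10] == 1.0)


class TestSummarize:
    def test_constant_series(self):
        series = SyncSeries(np.arange(10) * DT, np.full(10, 0.4), np.full(10, 5))
        s = summarize_sync(series)
        assert s.k_mean == pytest.approx(0.4) and s.k_std == pytest.approx(0.0)

    def test_alternating_series_mean(self):
        k = np.tile([0.2, 0.8], 50)
        s = summarize_sync(SyncSeries(np.arange(100) * DT, k, np.full(100, 5)))
        assert s.k_mean == pytest.approx(0.5)

    def test_empty_interval_rejected(self):
        series = SyncSeries(np.arange(10) * DT, np.full(10, 0.4), np.full(10, 5))
        with pytest.raises(ValueError):
            summarize_sync(series, interval_s=(8.0, 4.0))


class TestPipelineEndToEnd:
    def test_desynchronised_population_low_k(self, desynchronised_population):
        """Uncoupled cells: K̄ at the finite-size floor ≈ 0.886/√30 ≈ 0.16, ≤ 0.3."""
        _, (traces, _) = desynchronised_population
        result = analyze_traces(traces, interval_s=(410, 1800))
        assert result.sync_summary.k_mean <= 0.3

    def test_noise_free_synchronised_plateau_k(self):
        cfg = PopulationConfig(n_cells=40, coupling_scale=3.0, period_sd_s=3.0,
                               phase_noise_intensity=0.0, poisson_noise=False,
                               density_pct=0.3, seed=23)
        traces, _ = simulate_population(cfg)
        result = analyze_traces(traces, interval_s=(500, 1800))
        assert result.sync_summary.k_mean >= 0.95
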