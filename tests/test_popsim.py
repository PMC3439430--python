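"""Simulator: phase dynamics, coupling law, photon emission."""

import dataclasses
import math

import numpy as np
import pytest

from glycosync import popsim
from glycosync.popsim import (
    PERIOD_BAND_S,
    PopulationConfig,
    critical_coupling,
    density_to_coupling,
    simulate_phases,
    simulate_population,
    synthesize_traces,
)


def order_param(phases_at_t):
    """Direct complex-sum oracle for the order parameter."""
    return np.abs(np.mean(np.exp(1j * np.asarray(phases_at_t))))


class TestPhaseDynamics:
    def test_free_rotation_matches_closed_form(self):
        """With no coupling or noise the unwrapped phase advances 2π per period."""
        cfg = PopulationConfig(n_cells=4, coupling_scale=0.0, period_mean_s=40.0,
                               period_sd_s=0.0, phase_noise_intensity=0.0,
                               duration_s=400.0, seed=3)
        t, phases, periods = simulate_phases(cfg)
        assert np.allclose(periods, 40.0)
        expected = phases[:, :1] + 2 * np.pi * t[None, :] / 40.0
        assert np.allclose(phases, expected, atol=1e-8)

    def test_uncoupled_identical_oscillators_keep_phase_differences(self):
        cfg = PopulationConfig(n_cells=6, coupling_scale=0.0, period_sd_s=0.0,
                               phase_noise_intensity=0.0, duration_s=300.0, seed=5)
        _, phases, _ = simulate_phases(cfg)
        diffs = phases - phases[0]
        assert np.allclose(diffs, diffs[:, :1], atol=1e-8)

    def test_coupling_synchronises_population(self):
        """Strong coupling raises the order parameter over the run (Eq.-5 oracle)."""
        cfg = PopulationConfig(n_cells=50, coupling_scale=3.0, period_sd_s=3.0,
                               phase_noise_intensity=0.001, density_pct=0.3, seed=1)
        _, phases, _ = simulate_phases(cfg)
        quarter = phases.shape[1] // 4
        k_initial = order_param(phases[:, 0])
        k_final = np.mean([order_param(phases[:, j]) for j in range(-quarter, 0)])
        assert k_final > k_initial

    def test_periods_clipped_to_supported_band(self):
        cfg = PopulationConfig(n_cells=400, period_mean_s=40.0, period_sd_s=30.0,
                               duration_s=10.0, seed=2)
        _, _, periods = simulate_phases(cfg)
        assert periods.min() >= PERIOD_BAND_S[0]
        assert periods.max() <= PERIOD_BAND_S[1]

    def test_deterministic_given_seed(self):
        cfg = PopulationConfig(n_cells=10, duration_s=200.0, seed=99)
        tr1, gt1 = simulate_population(cfg)
        tr2, gt2 = simulate_population(cfg)
        assert np.array_equal(tr1.values, tr2.values)
        assert np.array_equal(gt1.phase, gt2.phase)

    def test_coarse_sampling_warns(self):
        cfg = PopulationConfig(n_cells=2, dt_s=8.0, period_mean_s=40.0,
                               duration_s=80.0, seed=0)
        with pytest.warns(UserWarning, match="integration accuracy"):
            simulate_phases(cfg)

    @pytest.mark.parametrize("bad", [
        {"n_cells": 0},
        {"dt_s": 0.0},
        {"duration_s": 1.0},
        {"period_mean_s": 10.0},
        {"density_pct": -0.1},
        {"amp_range_photons": (140.0, 60.0)},
        {"phase_noise_intensity": float("nan")},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            PopulationConfig(**bad).validate()


class TestCouplingLaw:
    def test_calibration_anchor(self):
        cfg = PopulationConfig()
        sigma_w = popsim.sigma_omega(cfg)
        assert density_to_coupling(0.3, cfg) == pytest.approx(critical_coupling(sigma_w))

    def test_linearity_in_density(self):
        cfg = PopulationConfig()
        assert density_to_coupling(0.6, cfg) == pytest.approx(2 * density_to_coupling(0.3, cfg))

    def test_density_must_be_positive(self):
        with pytest.raises(ValueError):
            density_to_coupling(0.0, PopulationConfig())

    def test_gaussian_threshold_formula(self):
        sigma = 0.0314
        assert critical_coupling(sigma) == pytest.approx(2 * sigma * math.sqrt(2 / math.pi))

    def test_threshold_located_numerically(self):
        """K̄ stays at the finite-size floor below g_c and rises well above it."""
        cfg = PopulationConfig(n_cells=400, period_sd_s=8.0, duration_s=1200.0,
                               phase_noise_intensity=0.0, seed=17)
        g_c = critical_coupling(popsim.sigma_omega(cfg))
        k_at = {}
        for mult in (0.3, 2.5):
            _, phases, _ = simulate_phases(cfg, coupling=mult * g_c)
            tail = phases[:, phases.shape[1] // 2:]
            k_at[mult] = np.mean([order_param(tail[:, j]) for j in range(0, tail.shape[1], 10)])
        assert k_at[0.3] < 0.2           # incoherent side: near 0.886/sqrt(400) ≈ 0.044
        assert k_at[2.5] > 0.5           # coherent side


class TestFiniteSizeLaw:
    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_random_phase_order_parameter(self, n, rng):
        """E[K] ≈ 0.886/√N for uniformly random phases (Monte Carlo)."""
        reps = 400
        ks = [order_param(rng.uniform(-np.pi, np.pi, n)) for _ in range(reps)]
        expected = 0.886 / math.sqrt(n)
        se = np.std(ks) / math.sqrt(reps)
        assert abs(np.mean(ks) - expected) < 4 * se + 0.01 * expected


class TestPhotonEmission:
    def test_zero_amplitude_noise_free_is_constant_baseline(self):
        cfg = PopulationConfig(n_cells=3, amp_range_photons=(0.0, 0.0),
                               baseline_photons=80.0, poisson_noise=False,
                               duration_s=200.0, seed=0)
        t, phases, periods = simulate_phases(cfg)
        traces, _ = synthesize_traces(t, phases, periods, cfg)
        assert np.allclose(traces.values, 80.0)

    def test_noise_free_trace_equals_deterministic_rate(self):
        """Disabling Poisson noise and the envelope reproduces the analytic sinusoid."""
        cfg = PopulationConfig(n_cells=2, poisson_noise=False, onset_mean_s=0.0,
                               onset_ramp_s=1e-6, exhaustion_s=1e9,
                               duration_s=300.0, seed=4)
        t, phases, periods = simulate_phases(cfg)
        traces, truth = synthesize_traces(t, phases, periods, cfg)
        amps = truth.amplitude_envelope
        expected = cfg.baseline_photons + amps * (1 + np.sin(phases)) / 2
        assert np.allclose(traces.values, expected)
        # past the (instant) onset the envelope is the flat per-cell amplitude
        assert np.allclose(amps[:, 1:], amps[:, 1:2])

    def test_poisson_sample_mean_matches_rate(self):
        """Sample mean within 3 standard errors of the time-averaged rate."""
        cfg = PopulationConfig(n_cells=1, baseline_photons=100.0,
                               amp_range_photons=(100.0, 100.0), onset_mean_s=0.0,
                               exhaustion_s=1e9, duration_s=8000.0, seed=8)
        t, phases, periods = simulate_phases(cfg)
        noisy, truth = synthesize_traces(t, phases, periods, cfg)
        rate = cfg.baseline_photons + truth.amplitude_envelope * (1 + np.sin(phases)) / 2
        n = t.size
        se = math.sqrt(rate.mean() / cfg.dt_s / n)  # var of photons/s per sample ≈ rate/dt
        assert abs(noisy.values.mean() - rate.mean()) < 3 * se

    def test_counts_non_negative(self, short_population):
        traces, _ = short_population
        assert traces.values.min() >= 0

    def test_ground_truth_one_record_per_cell(self, short_population):
        traces, truth = short_population
        n = traces.n_cells
        assert truth.natural_period_s.shape == (n,)
        assert truth.phase.shape[0] == n
        assert truth.amplitude_envelope.shape[0] == n
        assert np.all(truth.amplitude_envelope >= 0)
        assert np.all(np.isfinite(truth.phase))
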