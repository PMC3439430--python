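"""Synthetic populations of coupled glycolytic phase oscillators.

Individual yeast cells in starved, glucose-stimulated populations behave as
self-sustained oscillators whose NADH autofluorescence cycles with a natural
period of roughly 24–70 s.  Cell-to-cell coupling through an extracellular
messenger (acetaldehyde) is well approximated as a mean field whose strength
grows with cell density, so the population is modelled here as a stochastic
Kuramoto system:

    dφ_i = [ω_i + (g/N) Σ_j sin(φ_j − φ_i)] dt + √(2D) dW_i,   ω_i = 2π/T_i,

with natural periods ``T_i`` drawn from a Gaussian clipped to the supported
24–70 s band, and ``D`` a phase-diffusion coefficient representing intrinsic
metabolic noise.  Above the critical coupling the population phase-locks; below
it each cell keeps its own rhythm — exactly the density-dependent
synchronisation/desynchronisation transition the analysis pipeline is built to
detect.

Observable fluorescence is generated on top of the phases: a per-cell amplitude
envelope ramps up around the oscillation onset (~350 s after glucose addition)
and decays after glucose exhaustion, and photon emission is Poisson with the
instantaneous rate, matching photon-counting detection.

The density → coupling map is linear and calibrated so that the deterministic
mean-field threshold sits at 0.3 % w/v, the critical density at which real
populations lose coherence.  This bakes the transition density into the
generator as recoverable ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .traces import CellTraceSet

__all__ = [
    "PopulationConfig",
    "GroundTruth",
    "PERIOD_BAND_S",
    "CRITICAL_DENSITY_PCT",
    "CELLS_PER_ML_PER_PCT",
    "sigma_omega",
    "critical_coupling",
    "density_to_coupling",
    "simulate_phases",
    "synthesize_traces",
    "simulate_population",
]

#: Supported band of glycolytic oscillation periods (seconds).
PERIOD_BAND_S = (24.0, 70.0)

#: Cell density at which the deterministic coupling threshold is calibrated (% w/v).
CRITICAL_DENSITY_PCT = 0.3

#: Conversion used for reporting only: 1 % w/v ≈ 1.5e8 cells/ml.
CELLS_PER_ML_PER_PCT = 1.5e8

#: Euler–Maruyama substeps per output sample.
_SUBSTEPS = 10


@dataclass
class PopulationConfig:
    """All simulator parameters.

    Defaults describe a dense (0.7 % w/v) population sampled every 2 s for
    2000 s: oscillations start ≈350 s after glucose addition and decay after
    glucose exhaustion at ≈1800 s, with per-cell amplitudes of 60–140 photons/s
    on a 100 photons/s background.
    """

    n_cells: int = 50
    density_pct: float = 0.7
    dt_s: float = 2.0
    duration_s: float = 2000.0
    period_mean_s: float = 40.0
    period_sd_s: float = 8.0
    coupling_scale: float = 1.0
    phase_noise_intensity: float = 0.002  # rad^2/s
    onset_mean_s: float = 350.0
    onset_jitter_s: float = 0.0
    onset_ramp_s: float = 60.0
    exhaustion_s: float = 1800.0
    decay_tau_s: float = 150.0
    amp_range_photons: tuple[float, float] = (60.0, 140.0)
    baseline_photons: float = 100.0
    poisson_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        scalars = [
            self.density_pct, self.dt_s, self.duration_s, self.period_mean_s,
            self.period_sd_s, self.coupling_scale, self.phase_noise_intensity,
            self.onset_mean_s, self.onset_jitter_s, self.onset_ramp_s,
            self.exhaustion_s, self.decay_tau_s, self.baseline_photons,
            *self.amp_range_photons,
        ]
        if not all(np.isfinite(scalars)):
            raise ValueError("population config parameters must be finite")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_s < self.dt_s:
            raise ValueError("duration_s must cover at least one sampling interval")
        if not (PERIOD_BAND_S[0] <= self.period_mean_s <= PERIOD_BAND_S[1]):
            raise ValueError(
                f"period_mean_s must lie in the supported band {PERIOD_BAND_S}"
            )
        if self.period_sd_s < 0:
            raise ValueError("period_sd_s must be non-negative")
        lo, hi = self.amp_range_photons
        if not (0 <= lo <= hi):
            raise ValueError("amp_range_photons must be a non-empty interval of non-negative rates")
        if self.baseline_photons < 0:
            raise ValueError("baseline_photons must be non-negative")
        if self.density_pct <= 0:
            raise ValueError("density_pct must be positive")
        if self.phase_noise_intensity < 0:
            raise ValueError("phase_noise_intensity must be non-negative")

    @property
    def cells_per_ml(self) -> float:
        """Suspension density in cells/ml (reporting convenience)."""
        return self.density_pct * CELLS_PER_ML_PER_PCT

    def time_grid(self) -> np.ndarray:
        n_t = int(round(self.duration_s / self.dt_s)) + 1
        return np.arange(n_t) * self.dt_s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amp_range_photons"] = list(self.amp_range_photons)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        if "amp_range_photons" in d:
            d["amp_range_photons"] = tuple(d["amp_range_photons"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent simulator state, kept for parameter-recovery tests."""

    natural_period_s: np.ndarray          # (n_cells,)
    phase: np.ndarray                     # (n_cells, n_samples), unwrapped radians
    amplitude_envelope: np.ndarray        # (n_cells, n_samples), photons/s
    onset_s: np.ndarray                   # (n_cells,)
    offset_s: np.ndarray                  # (n_cells,)
    coupling: float
    positions_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase trajectories must be finite")
        if np.any(self.amplitude_envelope < 0):
            raise ValueError("amplitude envelopes must be non-negative")
        n = self.natural_period_s.size
        if self.phase.shape[0] != n or self.amplitude_envelope.shape[0] != n:
            raise ValueError("ground truth must carry one record per cell")


# ---------------------------------------------------------------------------
# coupling law
# ---------------------------------------------------------------------------

def sigma_omega(config: PopulationConfig) -> float:
    """Angular-frequency spread implied by the natural-period distribution.

    First-order (delta-method) propagation of the period sd through
    ω = 2π/T: σ_ω ≈ 2π σ_T / T̄².
    """
    return 2.0 * math.pi * config.period_sd_s / config.period_mean_s ** 2


def critical_coupling(sigma_omega_rad_s: float) -> float:
    """Mean-field Kuramoto threshold for Gaussian natural frequencies.

    g_c = 2/(π g(0)) with g(0) the frequency density at the mode, giving
    g_c = 2 σ_ω √(2/π) for a Gaussian of standard deviation σ_ω.
    """
    if sigma_omega_rad_s < 0:
        raise ValueError("sigma_omega must be non-negative")
    return 2.0 * sigma_omega_rad_s * math.sqrt(2.0 / math.pi)


def density_to_coupling(density_pct: float, config: PopulationConfig) -> float:
    """Linear density → mean-field coupling, anchored at the critical density.

    g(ρ) = g_c · (ρ / 0.3 %) · coupling_scale, so that with the default scale
    the deterministic synchronisation threshold sits exactly at 0.3 % w/v.
    """
    if density_pct <= 0:
        raise ValueError("density_pct must be positive")
    g_c = critical_coupling(sigma_omega(config))
    return g_c * (density_pct / CRITICAL_DENSITY_PCT) * config.coupling_scale


# ---------------------------------------------------------------------------
# phase dynamics
# ---------------------------------------------------------------------------

def _streams(config: PopulationConfig) -> list[np.random.Generator]:
    """Four independent, reproducible streams: init, dynamics, envelope, emission."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)]


def simulate_phases(
    config: PopulationConfig,
    coupling: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the mean-field Kuramoto SDE.

    Parameters
    ----------
    config
        Simulator parameters; randomness derives entirely from ``config.seed``.
    coupling
        Mean-field coupling g in rad/s.  Defaults to
        :func:`density_to_coupling` evaluated at ``config.density_pct``.

    Returns
    -------
    time_s, phases, periods
        ``time_s`` is the output grid; ``phases`` has shape
        ``(n_cells, n_samples)`` and is continuous (unwrapped); ``periods`` are
        the per-cell natural periods in seconds.

    Notes
    -----
    Explicit Euler–Maruyama with internal step ``dt_s/10``, subsampled to the
    output grid.  The mean-field sum is evaluated through the complex order
    parameter, so one step costs O(N).
    """
    config.validate()
    if config.dt_s > config.period_mean_s / 10.0:
        warnings.warn(
            f"dt_s={config.dt_s} s exceeds period_mean_s/10="
            f"{config.period_mean_s / 10.0:.2f} s; integration accuracy degrades",
            stacklevel=2,
        )
    if coupling is None:
        coupling = density_to_coupling(config.density_pct, config)

    rng_init, rng_dyn, _, _ = _streams(config)
    n = config.n_cells
    periods = rng_init.normal(config.period_mean_s, config.period_sd_s, size=n)
    periods = np.clip(periods, *PERIOD_BAND_S)
    omega = 2.0 * math.pi / periods

    time_s = config.time_grid()
    n_t = time_s.size
    h = config.dt_s / _SUBSTEPS
    noise_scale = math.sqrt(2.0 * config.phase_noise_intensity * h)

    phi = rng_init.uniform(-math.pi, math.pi, size=n)
    out = np.empty((n, n_t))
    out[:, 0] = phi
    for k in range(1, n_t):
        for _ in range(_SUBSTEPS):
            z = np.mean(np.exp(1j * phi))
            drift = omega + coupling * np.abs(z) * np.sin(np.angle(z) - phi)
            phi = phi + drift * h
            if noise_scale > 0:
                phi = phi + noise_scale * rng_dyn.standard_normal(n)
        out[:, k] = phi
    return time_s, out, periods


# ---------------------------------------------------------------------------
# photon emission
# ---------------------------------------------------------------------------

def _envelope(
    time_s: np.ndarray,
    onsets: np.ndarray,
    config: PopulationConfig,
) -> np.ndarray:
    """Smooth onset ramp times post-exhaustion exponential decay, in [0, 1]."""
    t = time_s[None, :]
    ramp_scale = max(config.onset_ramp_s, 1e-9) / 4.0  # logistic 10–90 % rise ≈ onset_ramp_s
    rise = 1.0 / (1.0 + np.exp(-(t - onsets[:, None]) / ramp_scale))
    # exponent clipped at 0 so the pre-exhaustion branch is exactly 1
    decay = np.exp(np.clip(-(t - config.exhaustion_s) / max(config.decay_tau_s, 1e-9),
                           -745.0, 0.0))
    return rise * decay


def synthesize_traces(
    time_s: np.ndarray,
    phases: np.ndarray,
    periods: np.ndarray,
    config: PopulationConfig,
    coupling: float | None = None,
    positions_um: np.ndarray | None = None,
) -> tuple[CellTraceSet, GroundTruth]:
    """Turn phase trajectories into observed photon-rate traces.

    The deterministic rate is ``F_i(t) = baseline + A_i(t) (1 + sin φ_i(t))/2``
    photons/s with ``A_i(t)`` the per-cell amplitude envelope.  With
    ``config.poisson_noise`` each sample records a Poisson count with mean
    ``F_i(t)·dt_s``, reported back as photons/s; otherwise the exact rate is
    returned (noise-free limit).
    """
    config.validate()
    if coupling is None:
        coupling = density_to_coupling(config.density_pct, config)
    phases = np.atleast_2d(phases)
    n = phases.shape[0]
    _, _, rng_env, rng_emit = _streams(config)

    onsets = config.onset_mean_s + config.onset_jitter_s * rng_env.standard_normal(n)
    onsets = np.clip(onsets, 0.0, None)
    amps = rng_env.uniform(*config.amp_range_photons, size=n)
    envelope = amps[:, None] * _envelope(np.asarray(time_s, float), onsets, config)

    rate = config.baseline_photons + envelope * (1.0 + np.sin(phases)) / 2.0
    if np.any(rate < 0):  # impossible by construction
        raise AssertionError("internal invariant violated: negative photon rate")
    if config.poisson_noise:
        values = rng_emit.poisson(rate * config.dt_s) / config.dt_s
    else:
        values = rate

    traces = CellTraceSet(
        time_s=np.asarray(time_s, float),
        values=values.astype(float),
        centroids_um=positions_um,
        stage="raw",
    )
    truth = GroundTruth(
        natural_period_s=np.asarray(periods, float),
        phase=phases,
        amplitude_envelope=envelope,
        onset_s=onsets,
        offset_s=np.full(n, float(config.exhaustion_s)),
        coupling=float(coupling),
        positions_um=positions_um,
    )
    return traces, truth


def simulate_population(
    config: PopulationConfig,
    with_positions: bool = False,
) -> tuple[CellTraceSet, GroundTruth]:
    """Convenience wrapper: phases → traces + ground truth in one call.

    With ``with_positions`` each cell is also given a non-overlapping position
    inside the circular field of view (needed for rendering frame stacks and
    for adjacent-cell period comparisons).
    """
    coupling = density_to_coupling(config.density_pct, config)
    time_s, phases, periods = simulate_phases(config, coupling=coupling)
    positions = None
    if with_positions:
        from .imaging import place_cells  # local import: imaging depends on popsim types

        _, _, rng_env, _ = _streams(config)
        # dedicated child stream so emission noise is unaffected by placement
        positions = place_cells(config.n_cells, rng=np.random.default_rng(rng_env.integers(2**31)))
    return synthesize_traces(time_s, phases, periods, config,
                             coupling=coupling, positions_um=positions)
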