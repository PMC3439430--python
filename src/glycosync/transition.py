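"""Density sweeps and the synchronisation–desynchronisation transition.

A sweep simulates replicate populations across a range of cell densities,
pushes each through the full analysis pipeline, and tabulates
(ρ, K̄, σ_K, σ_T, gaussian σ, n_oscillating).  The critical density ρ_c is the
midpoint of a logistic fitted to K̄ versus log₁₀ ρ — the density at which K̄
crosses half-way between the fitted incoherent and coherent plateaus — with a
95 % interval propagated from the fit covariance.  A σ_T-based changepoint
(first density, descending, whose median σ_T exceeds the 2 s sampling
interval) is reported alongside for frequency-coherence comparability, and the
density below which the collective (summed) signal stops passing the
oscillation classifier is reported descriptively.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special

from . import pipeline, popsim, spectral
from .popsim import PopulationConfig

__all__ = [
    "SweepResult",
    "CriticalDensityFit",
    "default_n_cells",
    "run_density_sweep",
    "estimate_critical_density",
]

#: σ_T above this (the sampling interval, seconds) marks frequency decoherence.
COHERENCE_SIGMA_T_S = 2.0

#: Cells inside the 169 µm field of view per % w/v plating density.
CELLS_PER_PCT = 330.0


def default_n_cells(
    density_pct: float,
    cells_per_pct: float = CELLS_PER_PCT,
    min_cells: int = 10,
    max_cells: int = 100,
) -> int:
    """Density-proportional cell count, clipped for statistics and tractability."""
    return int(np.clip(round(density_pct * cells_per_pct), min_cells, max_cells))


@dataclass
class SweepResult:
    """Per-replicate summary rows plus the sweep configuration snapshot."""

    table: pd.DataFrame
    base_config: PopulationConfig
    densities_pct: tuple[float, ...]
    replicates: int
    master_seed: int

    def mean_by_density(self) -> pd.DataFrame:
        ok = self.table[self.table["error"].isna()]
        return ok.groupby("density_pct").agg(
            k_mean=("k_mean", "mean"),
            k_mean_sd=("k_mean", "std"),
            k_std=("k_std", "mean"),
            sigma_t_s=("sigma_t_s", "median"),
            gaussian_sigma_s=("gaussian_sigma_s", "median"),
            n_oscillating=("n_oscillating", "mean"),
        ).reset_index()

    def fig_exports(self) -> dict[str, pd.DataFrame]:
        """Plot-ready tables: K̄ ± σ_K vs density and σ_T vs density."""
        m = self.mean_by_density()
        return {
            "order_parameter_vs_density": m[["density_pct", "k_mean", "k_std"]],
            "period_dispersion_vs_density": m[["density_pct", "sigma_t_s", "gaussian_sigma_s"]],
        }


def _replicate_row(
    config: PopulationConfig,
    density_pct: float,
    replicate: int,
    seed: int,
) -> dict:
    row = {
        "density_pct": density_pct,
        "replicate": replicate,
        "seed": seed,
        "n_cells": config.n_cells,
        "k_mean": np.nan,
        "k_std": np.nan,
        "sigma_t_s": np.nan,
        "gaussian_sigma_s": np.nan,
        "n_oscillating": np.nan,
        "collective_oscillating": np.nan,
        "error": None,
    }
    try:
        traces, truth = popsim.simulate_population(config)
        interval = (
            config.onset_mean_s + config.onset_ramp_s,
            config.exhaustion_s,
        )
        result = pipeline.analyze_traces(traces, interval_s=interval)
        row["k_mean"] = result.sync_summary.k_mean
        row["k_std"] = result.sync_summary.k_std
        row["sigma_t_s"] = result.period_stats.sigma_t_s
        row["gaussian_sigma_s"] = result.period_stats.gaussian_sigma_s
        row["n_oscillating"] = result.period_stats.n_oscillating

        collective = traces.collective_signal()
        est = spectral.estimate_period(collective - collective.mean(), traces.dt_s)
        thr = spectral.oscillation_threshold(traces.n_samples, round(traces.dt_s, 9))
        row["collective_oscillating"] = spectral.classify_oscillating(est.peak_fraction, thr)
    except Exception as exc:  # row-level failure: record, keep sweeping
        row["error"] = f"{type(exc).__name__}: {exc}"
    return row


def run_density_sweep(
    base_config: PopulationConfig,
    densities_pct: list[float] | np.ndarray,
    replicates: int = 10,
    n_cells_rule: str = "density",
    min_cells: int = 10,
    max_cells: int = 100,
) -> SweepResult:
    """Simulate and analyse ``replicates`` populations at each density.

    Seeds are split deterministically from ``base_config.seed`` (the master
    seed), so a sweep is exactly reproducible.  With the default
    ``n_cells_rule="density"`` the per-replicate cell count follows
    :func:`default_n_cells`; ``"fixed"`` keeps ``base_config.n_cells``
    everywhere.  Failures are recorded per row; the sweep continues.
    """
    densities = [float(d) for d in np.atleast_1d(densities_pct)]
    if len(densities) == 0:
        raise ValueError("densities must be a non-empty list")
    if any(d <= 0 for d in densities):
        raise ValueError("densities must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n_cells_rule not in ("density", "fixed"):
        raise ValueError("n_cells_rule must be 'density' or 'fixed'")

    children = np.random.SeedSequence(base_config.seed).spawn(len(densities) * replicates)
    rows = []
    idx = 0
    for d in densities:
        n_cells = (
            default_n_cells(d, min_cells=min_cells, max_cells=max_cells)
            if n_cells_rule == "density"
            else base_config.n_cells
        )
        for r in range(replicates):
            seed = int(children[idx].generate_state(1)[0] % 2**31)
            idx += 1
            cfg = dataclasses.replace(base_config, density_pct=d, n_cells=n_cells, seed=seed)
            rows.append(_replicate_row(cfg, d, r, seed))
    return SweepResult(
        table=pd.DataFrame(rows),
        base_config=base_config,
        densities_pct=tuple(densities),
        replicates=replicates,
        master_seed=base_config.seed,
    )


# ---------------------------------------------------------------------------
# critical-density estimation
# ---------------------------------------------------------------------------

def _logistic(x, k_lo, k_hi, x0, width):
    return k_lo + (k_hi - k_lo) * scipy.special.expit((x - x0) / width)


@dataclass
class CriticalDensityFit:
    """Results object for the logistic transition fit.

    ``rho_c_pct`` is None when no transition is detected (K̄ essentially flat
    across the sweep).
    """

    transition_detected: bool
    rho_c_pct: float | None
    rho_c_ci95_pct: tuple[float, float] | None
    params: dict | None
    sigma_t_changepoint_pct: float | None
    collective_quiescent_below_pct: float | None
    message: str

    def summary(self) -> str:
        lines = ["Critical-density logistic fit", "-" * 33]
        if not self.transition_detected:
            lines.append(f"no transition detected: {self.message}")
        else:
            lo, hi = self.rho_c_ci95_pct
            lines += [
                f"rho_c              {self.rho_c_pct:8.3f} % w/v",
                f"95% CI             [{lo:.3f}, {hi:.3f}] % w/v",
                f"incoherent plateau {self.params['k_lo']:8.3f}",
                f"coherent plateau   {self.params['k_hi']:8.3f}",
                f"logistic width     {self.params['width']:8.3f} decades",
            ]
        if self.sigma_t_changepoint_pct is not None:
            lines.append(
                f"sigma_T > {COHERENCE_SIGMA_T_S:.0f} s below   "
                f"{self.sigma_t_changepoint_pct:8.3f} % w/v"
            )
        if self.collective_quiescent_below_pct is not None:
            lines.append(
                f"collective signal quiescent at {self.collective_quiescent_below_pct:8.3f} % w/v and below"
            )
        return "\n".join(lines)


def estimate_critical_density(sweep: SweepResult | pd.DataFrame) -> CriticalDensityFit:
    """Locate the synchronisation transition density from a sweep table.

    Fits ``K̄ = k_lo + (k_hi − k_lo) / (1 + exp(−(log₁₀ρ − x0)/w))`` to all
    replicate rows and reports ρ_c = 10^x0 (the half-way crossing between the
    fitted plateaus) with a 95 % interval from the covariance of x0.  The
    estimate is invariant to row order and to duplicating rows.  A sweep whose
    K̄ range never rises meaningfully (span < 0.2) yields a no-transition
    result instead of a number.
    """
    table = sweep.table if isinstance(sweep, SweepResult) else sweep
    ok = table[table["error"].isna() & np.isfinite(table["k_mean"])]
    if ok.empty:
        return CriticalDensityFit(False, None, None, None, None, None,
                                  "no successful sweep rows")

    means = ok.groupby("density_pct")["k_mean"].mean().sort_index()
    sigma_cp = _sigma_t_changepoint(ok)
    quiescent = _collective_quiescence(ok)

    if means.max() - means.min() < 0.2:
        kind = "high" if means.mean() > 0.5 else "low"
        return CriticalDensityFit(
            False, None, None, None, sigma_cp, quiescent,
            f"order parameter is uniformly {kind} (span "
            f"{means.max() - means.min():.3f}) across the sweep",
        )

    x = np.log10(ok["density_pct"].to_numpy(float))
    y = ok["k_mean"].to_numpy(float)
    # midway-crossing initial guess from the density-averaged profile
    xm = np.log10(means.index.to_numpy(float))
    ym = means.to_numpy(float)
    half = (ym.min() + ym.max()) / 2.0
    above = np.nonzero(ym >= half)[0]
    x0_guess = xm[above[0]] if above.size else xm[-1]
    p0 = (float(ym.min()), float(ym.max()), float(x0_guess), 0.2)
    try:
        popt, pcov = scipy.optimize.curve_fit(
            _logistic, x, y, p0=p0,
            bounds=([0.0, 0.0, x.min() - 1.0, 1e-3], [1.0, 1.0, x.max() + 1.0, 5.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return CriticalDensityFit(False, None, None, None, sigma_cp, quiescent,
                                  f"logistic fit failed: {exc}")

    k_lo, k_hi, x0, width = popt
    se_x0 = math.sqrt(max(pcov[2, 2], 0.0))
    rho_c = 10.0 ** x0
    ci = (10.0 ** (x0 - 1.96 * se_x0), 10.0 ** (x0 + 1.96 * se_x0))
    return CriticalDensityFit(
        transition_detected=True,
        rho_c_pct=float(rho_c),
        rho_c_ci95_pct=(float(ci[0]), float(ci[1])),
        params={"k_lo": float(k_lo), "k_hi": float(k_hi),
                "x0_log10": float(x0), "width": float(width),
                "x0_se": float(se_x0)},
        sigma_t_changepoint_pct=sigma_cp,
        collective_quiescent_below_pct=quiescent,
        message="ok",
    )


def _sigma_t_changepoint(ok: pd.DataFrame) -> float | None:
    """First density, descending, whose median σ_T exceeds the 2 s criterion."""
    med = ok.groupby("density_pct")["sigma_t_s"].median().sort_index(ascending=False)
    for density, value in med.items():
        if np.isfinite(value) and value > COHERENCE_SIGMA_T_S:
            return float(density)
    return None


def _collective_quiescence(ok: pd.DataFrame) -> float | None:
    """Highest density at which most replicates' collective signal fails the
    oscillation classifier (descriptive second threshold)."""
    if "collective_oscillating" not in ok or ok["collective_oscillating"].isna().all():
        return None
    frac = ok.groupby("density_pct")["collective_oscillating"].mean().sort_index(ascending=False)
    for density, value in frac.items():
        if value < 0.5:
            return float(density)
    return None
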