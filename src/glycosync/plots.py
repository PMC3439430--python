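"""Plot helpers for sweep results (transition curves).

Thin wrappers over matplotlib; everything they draw comes from the
machine-readable sweep tables, so plots are optional and never load-bearing.
"""

from __future__ import annotations

import numpy as np

from .transition import COHERENCE_SIGMA_T_S, CriticalDensityFit, SweepResult

__all__ = ["plot_order_parameter_vs_density", "plot_period_dispersion_vs_density"]


def plot_order_parameter_vs_density(sweep: SweepResult, fit: CriticalDensityFit | None = None, ax=None):
    """K̄ ± σ_K against cell density on a log axis, with the fitted transition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = sweep.mean_by_density()
    ax.errorbar(m["density_pct"], m["k_mean"], yerr=m["k_std"], fmt="o", capsize=3)
    if fit is not None and fit.transition_detected:
        x = np.logspace(np.log10(m["density_pct"].min()), np.log10(m["density_pct"].max()), 200)
        p = fit.params
        y = p["k_lo"] + (p["k_hi"] - p["k_lo"]) / (
            1.0 + np.exp(-(np.log10(x) - p["x0_log10"]) / p["width"])
        )
        ax.plot(x, y, "-", alpha=0.7)
        ax.axvline(fit.rho_c_pct, ls="--", color="gray")
    ax.set_xscale("log")
    ax.set_xlabel("cell density (% w/v)")
    ax.set_ylabel(r"time-averaged order parameter $\bar{K}$")
    ax.set_ylim(0, 1.05)
    return ax


def plot_period_dispersion_vs_density(sweep: SweepResult, ax=None):
    """Median σ_T against cell density with the 2 s coherence line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = sweep.mean_by_density()
    ax.plot(m["density_pct"], m["sigma_t_s"], "o")
    ax.axhline(COHERENCE_SIGMA_T_S, ls="--", color="gray")
    ax.set_xscale("log")
    ax.set_xlabel("cell density (% w/v)")
    ax.set_ylabel(r"period dispersion $\sigma_T$ (s)")
    return ax
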