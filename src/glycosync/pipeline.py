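"""End-to-end analysis: raw traces → periods, phases, and synchrony summary.

The canonical chain is

    (smooth) → subtract_baseline → bandpass_filter → {period statistics,
    Hilbert phases → K(t) → (K̄, σ_K)}

with the order parameter computed, by default, over oscillating cells only and
with the first/last half oscillation period masked against Hilbert endpoint
artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess, spectral, synchrony
from .preprocess import GLYCOLYTIC_BAND_HZ
from .traces import CellTraceSet

__all__ = ["AnalysisResult", "analyze_traces"]


@dataclass
class AnalysisResult:
    """Everything the pipeline derives from one trace set."""

    traces_filtered: CellTraceSet
    amplitude_table: pd.DataFrame
    period_stats: spectral.PeriodStats
    phases: synchrony.PhaseSet
    sync_series: synchrony.SyncSeries
    sync_summary: synchrony.SyncSummary

    def to_summary_dict(self) -> dict:
        return {
            "sync": self.sync_summary.to_dict(),
            "periods": self.period_stats.to_dict(),
        }


def analyze_traces(
    traces: CellTraceSet,
    f_lo: float = GLYCOLYTIC_BAND_HZ[0],
    f_hi: float = GLYCOLYTIC_BAND_HZ[1],
    smooth_window: int | None = None,
    period_hint_s: float | None = None,
    interval_s: tuple[float, float] | None = None,
    oscillating_only: bool = True,
    osc_threshold: float | None = None,
    edge_exclude_s: float | str | None = "half-period",
) -> AnalysisResult:
    """Run the full synchrony pipeline on a raw trace set.

    Parameters
    ----------
    traces
        Raw per-cell photon-rate traces.
    f_lo, f_hi
        Bandpass cutoffs in Hz.
    smooth_window
        Optional odd window for adjacent-average smoothing (off by default).
    period_hint_s
        Walking-average baseline window in seconds; per-cell FFT estimate when
        omitted.
    interval_s
        Averaging interval for (K̄, σ_K); full series when omitted.
    oscillating_only
        Restrict the order parameter to cells passing the oscillation
        criterion (falls back to all cells, with a warning, when fewer than
        two qualify).
    osc_threshold
        Peak-power-fraction threshold; Monte-Carlo null default.
    edge_exclude_s
        Seconds masked at both ends of K(t); the default string
        ``"half-period"`` uses half the median oscillating period.  ``None``
        disables the masking.
    """
    band = (f_lo, f_hi)
    work = traces
    if smooth_window is not None:
        work = preprocess.smooth_adjacent(work, smooth_window)
    detrended = preprocess.subtract_baseline(work, period_hint_s=period_hint_s, band=band)
    filtered = preprocess.bandpass_filter(detrended, f_lo=f_lo, f_hi=f_hi)
    _, amplitude_table = preprocess.normalize_amplitudes(filtered)

    period_stats = spectral.period_statistics(filtered, band=band, threshold=osc_threshold)

    phases = synchrony.instantaneous_phase(filtered, band_hz=band)
    if oscillating_only:
        if period_stats.n_oscillating >= 2:
            phases_for_k = phases.subset(period_stats.oscillating)
        else:
            warnings.warn(
                "fewer than 2 oscillating cells; computing the order parameter "
                "over all cells",
                stacklevel=2,
            )
            phases_for_k = phases
    else:
        phases_for_k = phases

    if edge_exclude_s == "half-period":
        med = np.nanmedian(period_stats.period_s)
        edge_exclude_s = float(med) / 2.0 if np.isfinite(med) else None
    series = synchrony.order_parameter_series(phases_for_k, edge_exclude_s=edge_exclude_s)
    summary = synchrony.summarize_sync(series, interval_s=interval_s)

    return AnalysisResult(
        traces_filtered=filtered,
        amplitude_table=amplitude_table,
        period_stats=period_stats,
        phases=phases,
        sync_series=series,
        sync_summary=summary,
    )
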