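"""Conditioning of raw per-cell fluorescence traces.

Four stages, each optional and each preserving the time grid:

1. adjacent averaging (centred 3-point moving mean, presentation smoothing),
2. walking-average baseline subtraction with a one-period window, which
   removes slow drifts and leaves oscillations around zero,
3. brick-wall Fourier bandpass keeping 0.014–0.05 Hz, the glycolytic band,
4. amplitude normalisation against the cell with the largest oscillatory
   amplitude in the population.

The bandpass zeroes DFT coefficients outside the band exactly (no taper); the
resulting edge ringing is the documented price of a literal spectral gate.
Moving means use truncated (shrinking) windows at the edges so output length
equals input length.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.signal

from .traces import CellTraceSet

__all__ = [
    "GLYCOLYTIC_BAND_HZ",
    "smooth_adjacent",
    "subtract_baseline",
    "bandpass_filter",
    "normalize_amplitudes",
]

#: Default spectral pass band for glycolytic oscillations (Hz).
GLYCOLYTIC_BAND_HZ = (0.014, 0.05)


def _moving_mean_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean with truncated windows at the edges.

    ``window`` is the nominal length in samples; for even windows the extra
    sample sits on the trailing side.
    """
    x = np.atleast_2d(x)
    n = x.shape[-1]
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    sums = cs[..., hi + 1] - cs[..., lo]
    return sums / (hi - lo + 1)


def smooth_adjacent(traces: CellTraceSet, window: int = 3) -> CellTraceSet:
    """Adjacent averaging over ``window`` consecutive data points.

    Window must be odd so the average is centred; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    return traces.with_values(_moving_mean_truncated(traces.values, window), stage="smoothed")


def _provisional_period(x: np.ndarray, dt_s: float, band: tuple[float, float]) -> float:
    """First-pass dominant period of a raw trace (mean removed), in seconds."""
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=dt_s)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any() or power[in_band].max() == 0:
        return float("nan")
    return 1.0 / freqs[in_band][np.argmax(power[in_band])]


def subtract_baseline(
    traces: CellTraceSet,
    period_hint_s: float | np.ndarray | None = None,
    band: tuple[float, float] = GLYCOLYTIC_BAND_HZ,
) -> CellTraceSet:
    """Subtract the walking-average baseline (window = one oscillation period).

    When ``period_hint_s`` is omitted, each cell's provisional period is taken
    from a first-pass FFT of its raw, mean-removed trace restricted to
    ``band``; cells with no in-band power fall back to the geometric centre of
    the band.  The subtraction removes any constant exactly and leaves a
    sinusoid whose period matches the window oscillating around zero.
    """
    dt = traces.dt_s
    if period_hint_s is None:
        hints = np.array([
            _provisional_period(row, dt, band) for row in traces.values
        ])
        fallback = 1.0 / np.sqrt(band[0] * band[1])
        hints = np.where(np.isfinite(hints), hints, fallback)
    else:
        hints = np.broadcast_to(np.asarray(period_hint_s, float), (traces.n_cells,)).copy()
        if np.any(~np.isfinite(hints)) or np.any(hints < 2 * dt):
            raise ValueError(f"period_hint_s must be finite and at least 2*dt_s = {2 * dt} s")

    out = np.empty_like(traces.values)
    for i, (row, hint) in enumerate(zip(traces.values, hints)):
        window = max(int(round(hint / dt)), 2)
        out[i] = row - _moving_mean_truncated(row, window)[0]
    return traces.with_values(out, stage="detrended")


def bandpass_filter(
    traces: CellTraceSet,
    f_lo: float = GLYCOLYTIC_BAND_HZ[0],
    f_hi: float = GLYCOLYTIC_BAND_HZ[1],
) -> CellTraceSet:
    """Brick-wall Fourier bandpass: zero all DFT coefficients outside [f_lo, f_hi].

    Bin-centred tones inside the band are preserved to rounding; tones outside
    (including DC) are removed to numerical zero.  Idempotent.
    """
    if f_lo >= f_hi:
        raise ValueError(f"f_lo ({f_lo}) must be below f_hi ({f_hi})")
    if f_lo <= 0:
        raise ValueError("f_lo must be positive")
    if traces.duration_s < 1.0 / f_lo:
        warnings.warn(
            f"trace ({traces.duration_s:.0f} s) is shorter than one period of "
            f"the lower cutoff ({1.0 / f_lo:.0f} s); the band edge is poorly resolved",
            stacklevel=2,
        )
    spec = np.fft.rfft(traces.values, axis=-1)
    freqs = np.fft.rfftfreq(traces.n_samples, d=traces.dt_s)
    spec[:, (freqs < f_lo) | (freqs > f_hi)] = 0.0
    return traces.with_values(np.fft.irfft(spec, n=traces.n_samples, axis=-1), stage="filtered")


def normalize_amplitudes(traces: CellTraceSet) -> tuple[CellTraceSet, pd.DataFrame]:
    """Normalise against the largest oscillatory amplitude in the population.

    The per-cell oscillating amplitude is the maximum of the Hilbert envelope
    of its (filtered) trace; all traces are divided by the largest such
    amplitude, so the loudest cell spans [-1, 1] up to envelope-estimation
    error.  Returns the rescaled traces and a per-cell amplitude table.
    """
    envelope = np.abs(scipy.signal.hilbert(traces.values, axis=-1))
    amplitudes = envelope.max(axis=-1)
    norm = amplitudes.max()
    if norm == 0:
        raise ValueError("all traces are identically zero: normalisation undefined")
    table = pd.DataFrame(
        {
            "cell_id": np.asarray(traces.cell_ids),
            "amplitude": amplitudes,
            "normalised_amplitude": amplitudes / norm,
        }
    )
    return traces.with_values(traces.values / norm, stage="normalised"), table
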