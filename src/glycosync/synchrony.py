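"""Hilbert phases and the Shinomoto–Kuramoto order parameter.

Each band-limited, zero-mean cell signal s_i(t) defines an analytic signal
s_i + i·H[s_i] whose angle is the instantaneous phase

    φ_i(t) = atan2( H[s_i](t), s_i(t) ).

Phase coherence across the population is measured by the order parameter

    K(t) = | (1/N) Σ_i exp(i φ_i(t)) |,

which is 1 for identical phases, ~0.886/√N for independent random phases, and
0 for perfectly balanced antiphase configurations.  A measurement is
summarised by the time average K̄ and the spread σ_K of K(t) over an
averaging interval, conventionally the window between oscillation onset and
amplitude decay (including the pre-onset transient would bias K̄ down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .traces import CellTraceSet

__all__ = [
    "PhaseSet",
    "SyncSeries",
    "SyncSummary",
    "instantaneous_phase",
    "order_parameter_series",
    "summarize_sync",
]


@dataclass
class PhaseSet:
    """Per-cell instantaneous phases on the shared time grid.

    ``wrapped`` lies in (−π, π]; ``unwrapped`` is the continuous version,
    differing pointwise by integer multiples of 2π.  Cells whose signal was
    identically zero have undefined phase: their rows are NaN and they are
    flagged in ``undefined``.
    """

    time_s: np.ndarray
    wrapped: np.ndarray
    unwrapped: np.ndarray
    cell_ids: np.ndarray
    undefined: np.ndarray
    band_hz: tuple[float, float] | None = None

    @property
    def n_cells(self) -> int:
        return self.wrapped.shape[0]

    @property
    def dt_s(self) -> float:
        return float((self.time_s[-1] - self.time_s[0]) / (self.time_s.size - 1))

    def subset(self, mask: np.ndarray) -> "PhaseSet":
        mask = np.asarray(mask)
        return PhaseSet(
            time_s=self.time_s,
            wrapped=self.wrapped[mask],
            unwrapped=self.unwrapped[mask],
            cell_ids=np.asarray(self.cell_ids)[mask],
            undefined=np.asarray(self.undefined)[mask],
            band_hz=self.band_hz,
        )

    def to_frame(self) -> pd.DataFrame:
        n_c, n_t = self.wrapped.shape
        return pd.DataFrame(
            {
                "time_s": np.tile(self.time_s, n_c),
                "cell_id": np.repeat(np.asarray(self.cell_ids), n_t),
                "phase_rad": self.wrapped.ravel(),
                "phase_unwrapped_rad": self.unwrapped.ravel(),
            }
        )


@dataclass
class SyncSeries:
    """Time-resolved order parameter K(t) with per-sample cell counts.

    ``order_parameter`` is NaN where no cell had a usable phase (masked, not
    zero).
    """

    time_s: np.ndarray
    order_parameter: np.ndarray
    n_cells_used: np.ndarray

    def __post_init__(self) -> None:
        k = self.order_parameter[np.isfinite(self.order_parameter)]
        if k.size and (k.min() < -1e-12 or k.max() > 1 + 1e-9):
            raise ValueError("order parameter must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "order_parameter": self.order_parameter,
                "n_cells_used": self.n_cells_used,
            }
        )


@dataclass
class SyncSummary:
    """Time-averaged order parameter K̄ and its spread σ_K."""

    k_mean: float
    k_std: float
    interval_s: tuple[float, float]
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "k_mean": self.k_mean,
            "k_std": self.k_std,
            "interval_s": list(self.interval_s),
            "n_samples": self.n_samples,
        }


def instantaneous_phase(
    traces: CellTraceSet,
    band_hz: tuple[float, float] | None = None,
) -> PhaseSet:
    """Extract per-cell instantaneous phases via the Hilbert transform.

    Traces are expected to be bandpass-filtered and near zero-mean; the phase
    of each cell is the angle of its analytic signal, with the filtered signal
    as the real part.  Identically-zero traces yield an undefined phase for
    that cell (NaN, flagged, warned) while the remaining cells proceed.
    """
    values = traces.values
    undefined = ~np.any(values != 0.0, axis=-1)
    wrapped = np.full_like(values, np.nan)
    unwrapped = np.full_like(values, np.nan)
    if (~undefined).any():
        analytic = scipy.signal.hilbert(values[~undefined], axis=-1)
        w = np.angle(analytic)
        w[w == -np.pi] = np.pi
        wrapped[~undefined] = w
        unwrapped[~undefined] = np.unwrap(w, axis=-1)
    if undefined.any():
        bad = np.asarray(traces.cell_ids)[undefined]
        warnings.warn(
            f"phase undefined for identically-zero cells {bad.tolist()}; "
            "they are excluded from the order parameter",
            stacklevel=2,
        )
    return PhaseSet(
        time_s=traces.time_s,
        wrapped=wrapped,
        unwrapped=unwrapped,
        cell_ids=np.asarray(traces.cell_ids),
        undefined=undefined,
        band_hz=band_hz,
    )


def order_parameter_series(
    phases: PhaseSet | np.ndarray,
    time_s: np.ndarray | None = None,
    edge_exclude_s: float | None = None,
) -> SyncSeries:
    """K(t) = modulus of the population-mean unit phasor at each sample.

    Cells with undefined (NaN) phase at a sample are excluded and the count of
    usable cells recorded; samples with zero usable cells are masked (NaN).
    ``edge_exclude_s`` masks that many seconds at both ends of the series,
    where Hilbert endpoint artefacts distort the phases (a half period is a
    sensible choice).
    """
    if isinstance(phases, PhaseSet):
        angles = phases.wrapped
        time_s = phases.time_s
    else:
        angles = np.atleast_2d(np.asarray(phases, dtype=float))
        if time_s is None:
            raise ValueError("time_s is required when passing a bare phase array")
        time_s = np.asarray(time_s, dtype=float)

    finite = np.isfinite(angles)
    phasors = np.where(finite, np.exp(1j * np.where(finite, angles, 0.0)), 0.0)
    n_used = finite.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.abs(phasors.sum(axis=0)) / n_used
    k = np.where(n_used > 0, k, np.nan)
    # guard rounding excursions above 1
    k = np.where(np.isfinite(k), np.clip(k, 0.0, 1.0), k)

    if edge_exclude_s is not None and edge_exclude_s > 0:
        dt = (time_s[-1] - time_s[0]) / (time_s.size - 1)
        n_edge = int(round(edge_exclude_s / dt))
        if n_edge > 0:
            k = k.copy()
            k[:n_edge] = np.nan
            k[-n_edge:] = np.nan
    return SyncSeries(time_s=time_s, order_parameter=k, n_cells_used=n_used)


def summarize_sync(
    series: SyncSeries,
    interval_s: tuple[float, float] | None = None,
) -> SyncSummary:
    """Time-averaged order parameter K̄ and σ_K over ``interval_s``.

    The default interval is the full series; pass the onset-to-exhaustion
    window to exclude the pre-onset transient and the post-exhaustion decay.
    """
    t = series.time_s
    if interval_s is None:
        interval_s = (float(t[0]), float(t[-1]))
    t0, t1 = interval_s
    if t1 <= t0:
        raise ValueError(f"empty averaging interval ({t0}, {t1})")
    sel = (t >= t0) & (t <= t1) & np.isfinite(series.order_parameter)
    if not sel.any():
        raise ValueError(
            f"no usable order-parameter samples inside the interval ({t0}, {t1})"
        )
    k = series.order_parameter[sel]
    return SyncSummary(
        k_mean=float(k.mean()),
        k_std=float(k.std()),
        interval_s=(float(t0), float(t1)),
        n_samples=int(sel.sum()),
    )
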