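"""Per-cell photon-rate time series: the working currency of the pipeline.

A :class:`CellTraceSet` holds one fluorescence (photon-rate) series per cell on a
shared, uniformly spaced time grid, together with cell identities, optional cell
centroid positions, and a ``stage`` tag recording how far through the
preprocessing chain (raw → smoothed → detrended → filtered → normalised) the
values have travelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CellTraceSet", "STAGES"]

STAGES = ("raw", "smoothed", "detrended", "filtered", "normalised")

_GRID_RTOL = 1e-6


@dataclass
class CellTraceSet:
    """Per-cell series ``values[i, k]`` sampled at ``time_s[k]``.

    Parameters
    ----------
    time_s
        Strictly increasing, uniformly spaced sample times in seconds.
    values
        Array of shape ``(n_cells, n_samples)``; photon rates (photons/s) for
        raw traces, arbitrary (zero-mean / normalised) units downstream.
    cell_ids
        Integer identity per cell; defaults to ``0..n_cells-1``.
    centroids_um
        Optional ``(n_cells, 2)`` cell centre positions in micrometres.
    stage
        Free-form tag; canonical values listed in :data:`STAGES`.
    """

    time_s: np.ndarray
    values: np.ndarray
    cell_ids: np.ndarray | None = None
    centroids_um: np.ndarray | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise ValueError("time_s must be 1-D with at least two samples")
        if self.values.shape[1] != self.time_s.size:
            raise ValueError(
                f"values has {self.values.shape[1]} samples per cell but the "
                f"time grid has {self.time_s.size}"
            )
        diffs = np.diff(self.time_s)
        if np.any(diffs <= 0):
            raise ValueError("time_s must be strictly increasing")
        dt = diffs[0]
        if not np.allclose(diffs, dt, rtol=_GRID_RTOL, atol=_GRID_RTOL * dt):
            bad = np.nonzero(~np.isclose(diffs, dt, rtol=_GRID_RTOL, atol=_GRID_RTOL * dt))[0]
            raise ValueError(
                f"time grid is not uniform; offending intervals start at sample "
                f"indices {bad[:10].tolist()}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.size != self.values.shape[0]:
                raise ValueError("cell_ids length does not match number of cells")
            if np.unique(self.cell_ids).size != self.cell_ids.size:
                raise ValueError("cell_ids must be unique")
        if self.centroids_um is not None:
            self.centroids_um = np.asarray(self.centroids_um, dtype=float)
            if self.centroids_um.shape != (self.values.shape[0], 2):
                raise ValueError("centroids_um must have shape (n_cells, 2)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def dt_s(self) -> float:
        return float((self.time_s[-1] - self.time_s[0]) / (self.time_s.size - 1))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    # -- derived sets ----------------------------------------------------
    def with_values(self, values: np.ndarray, stage: str | None = None) -> "CellTraceSet":
        """Return a copy carrying new ``values`` (same grid / identities)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       stage=self.stage if stage is None else stage)

    def subset(self, mask: np.ndarray) -> "CellTraceSet":
        """Select cells by boolean mask or index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            cell_ids=self.cell_ids[mask],
            centroids_um=None if self.centroids_um is None else self.centroids_um[mask],
        )

    def collective_signal(self) -> np.ndarray:
        """Population (summed) signal per sample, in the units of ``values``."""
        return self.values.sum(axis=0)

    # -- tabular interchange ----------------------------------------------
    def to_long_frame(self, value_name: str = "value") -> pd.DataFrame:
        n_c, n_t = self.values.shape
        return pd.DataFrame(
            {
                "time_s": np.tile(self.time_s, n_c),
                "cell_id": np.repeat(np.asarray(self.cell_ids), n_t),
                value_name: self.values.ravel(),
            }
        )

    @classmethod
    def from_long_frame(
        cls,
        frame: pd.DataFrame,
        value_name: str = "value",
        stage: str = "raw",
    ) -> "CellTraceSet":
        dup = frame.duplicated(subset=["time_s", "cell_id"])
        if dup.any():
            raise ValueError(
                f"duplicated (time_s, cell_id) pairs at rows {frame.index[dup][:10].tolist()}"
            )
        wide = frame.pivot(index="cell_id", columns="time_s", values=value_name)
        if wide.isna().any().any():
            raise ValueError("missing (time_s, cell_id) combinations: ragged trace table")
        return cls(
            time_s=wide.columns.to_numpy(dtype=float),
            values=wide.to_numpy(dtype=float),
            cell_ids=wide.index.to_numpy(),
            stage=stage,
        )
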