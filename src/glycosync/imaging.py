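"""Synthetic photon-count frame stacks and per-cell trace extraction.

The imaging geometry mirrors position-sensitive single-photon-counting
microscopy of immobilised yeast: photons are binned into 512×512 frames at
0.33 µm/pixel over 2 s intervals, inside a circular field of view of 169 µm
diameter.  Rendering scatters each cell's per-sample photon count
multinomially over its disk of pixels (so photons are conserved exactly);
extraction inverts the operation via Eq.-style ROI averaging,

    F_i = P_i / |A_i|   (photons per pixel per sampling interval),

where P_i is the photon count inside the cell's pixel area A_i.  A basic
Otsu-threshold segmentation recovers ROIs from the time-summed image; real
recordings were marked by hand, so this stand-in is only meant for synthetic
fixtures with well-separated cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import skimage.filters
import skimage.measure

from .traces import CellTraceSet

__all__ = [
    "FrameStack",
    "CellROI",
    "DEFAULT_FRAME_SHAPE",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_FOV_DIAMETER_UM",
    "DEFAULT_CELL_RADIUS_UM",
    "place_cells",
    "render_frames",
    "segment_cells",
    "extract_cell_traces",
]

DEFAULT_FRAME_SHAPE = (512, 512)
DEFAULT_PIXEL_SIZE_UM = 0.33
DEFAULT_FOV_DIAMETER_UM = 169.0
DEFAULT_CELL_RADIUS_UM = 2.5


@dataclass
class FrameStack:
    """T × H × W stack of non-negative integer photon counts.

    Pixels outside the circular field of view are always zero.
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    dt_s: float = 2.0
    fov_diameter_um: float = DEFAULT_FOV_DIAMETER_UM

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if not np.issubdtype(self.frames.dtype, np.integer):
            if not np.allclose(self.frames, np.round(self.frames)):
                raise ValueError("photon counts must be integers")
            self.frames = self.frames.astype(np.int64)
        if self.frames.min() < 0:
            raise ValueError("photon counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s

    def fov_mask(self) -> np.ndarray:
        return _fov_mask(self.shape, self.pixel_size_um, self.fov_diameter_um)


@dataclass
class CellROI:
    """Pixel region occupied by one cell (0-based row/col indices)."""

    cell_id: int
    pixels: np.ndarray          # (n_px, 2) array of (row, col)
    centroid_um: tuple[float, float]
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or self.pixels.shape[0] == 0:
            raise ValueError("ROI must be a non-empty (n, 2) pixel index array")
        self.area_px = int(self.pixels.shape[0])


def _fov_mask(shape: tuple[int, int], pixel_size_um: float, fov_diameter_um: float) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r_px = fov_diameter_um / 2.0 / pixel_size_um
    return (rows - cy) ** 2 + (cols - cx) ** 2 <= r_px ** 2


def _disk_pixels(
    center_um: tuple[float, float],
    radius_um: float,
    shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Pixels whose centres lie inside the disk; centre_um in (x, y) = (col, row)."""
    cx = center_um[0] / pixel_size_um
    cy = center_um[1] / pixel_size_um
    r = radius_um / pixel_size_um
    r0, r1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, shape[0])
    c0, c1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, shape[1])
    rows, cols = np.mgrid[r0:r1, c0:c1]
    inside = (rows - cy) ** 2 + (cols - cx) ** 2 <= r ** 2
    return np.column_stack([rows[inside], cols[inside]])


def place_cells(
    n_cells: int,
    rng: np.random.Generator,
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM,
    fov_diameter_um: float = DEFAULT_FOV_DIAMETER_UM,
    min_gap_um: float = 0.5,
    max_tries: int = 20000,
) -> np.ndarray:
    """Random non-overlapping cell centres inside the circular field of view.

    Coordinates are (x, y) in micrometres with the origin at the field-of-view
    corner (pixel (0, 0)); the field centre sits at (D/2, D/2).  Raises when
    the requested cells cannot be placed within ``max_tries`` attempts.
    """
    centre = fov_diameter_um / 2.0
    r_max = centre - cell_radius_um
    min_sep = 2 * cell_radius_um + min_gap_um
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells of radius "
                f"{cell_radius_um} um in a {fov_diameter_um} um field"
            )
        tries += 1
        # uniform over the disk
        rho = r_max * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        p = np.array([centre + rho * np.cos(theta), centre + rho * np.sin(theta)])
        if all(np.hypot(*(p - q)) >= min_sep for q in positions):
            positions.append(p)
    return np.array(positions)


def render_frames(
    traces: CellTraceSet,
    positions_um: np.ndarray,
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM,
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    fov_diameter_um: float = DEFAULT_FOV_DIAMETER_UM,
    background_rate_photons_s: float = 0.0,
    scatter: str = "multinomial",
    rng: np.random.Generator | None = None,
) -> tuple[FrameStack, list[CellROI]]:
    """Render a frame stack from per-cell photon-rate traces.

    Each cell's per-sample photon count ``round(rate * dt)`` is distributed
    over its disk of pixels — multinomially (``scatter="multinomial"``) or
    deterministically as evenly as integer counts allow
    (``scatter="uniform"``).  Either way the photons inside each ROI sum
    exactly to the cell's input count, and frame totals equal the sum of
    per-cell counts plus background.

    Returns the stack together with the ground-truth ROIs used.
    """
    if scatter not in ("multinomial", "uniform"):
        raise ValueError("scatter must be 'multinomial' or 'uniform'")
    positions_um = np.asarray(positions_um, dtype=float)
    if positions_um.shape != (traces.n_cells, 2):
        raise ValueError("positions_um must have shape (n_cells, 2)")
    if rng is None:
        rng = np.random.default_rng(0)

    fov = _fov_mask(frame_shape, pixel_size_um, fov_diameter_um)
    n_t = traces.n_samples
    frames = np.zeros((n_t,) + tuple(frame_shape), dtype=np.int64)
    rois: list[CellROI] = []

    counts_all = np.round(traces.values * traces.dt_s).astype(np.int64)
    if counts_all.min() < 0:
        raise ValueError("photon rates must be non-negative")

    for i in range(traces.n_cells):
        pixels = _disk_pixels(tuple(positions_um[i]), cell_radius_um, frame_shape, pixel_size_um)
        if pixels.shape[0] == 0 or not fov[pixels[:, 0], pixels[:, 1]].all():
            raise ValueError(
                f"cell {traces.cell_ids[i]} does not fit inside the field of view"
            )
        rois.append(CellROI(cell_id=int(traces.cell_ids[i]), pixels=pixels,
                            centroid_um=(float(positions_um[i, 0]), float(positions_um[i, 1]))))
        n_px = pixels.shape[0]
        counts = counts_all[i]
        if scatter == "multinomial":
            draws = rng.multinomial(counts, np.full(n_px, 1.0 / n_px))
        else:
            base = counts[:, None] // n_px
            rem = counts[:, None] - base * n_px
            draws = base + (np.arange(n_px)[None, :] < rem)
        np.add.at(frames, (slice(None), pixels[:, 0], pixels[:, 1]), draws)

    if background_rate_photons_s > 0:
        fov_idx = np.argwhere(fov)
        totals = rng.poisson(background_rate_photons_s * traces.dt_s, size=n_t)
        draws = rng.multinomial(totals, np.full(fov_idx.shape[0], 1.0 / fov_idx.shape[0]))
        np.add.at(frames, (slice(None), fov_idx[:, 0], fov_idx[:, 1]), draws)

    # overlap check: disjointness of rendered ROIs
    occupancy = np.zeros(frame_shape, dtype=np.int64)
    for roi in rois:
        occupancy[roi.pixels[:, 0], roi.pixels[:, 1]] += 1
    if occupancy.max() > 1:
        raise ValueError("rendered cells overlap; provide non-overlapping positions")

    stack = FrameStack(frames=frames, pixel_size_um=pixel_size_um,
                       dt_s=traces.dt_s, fov_diameter_um=fov_diameter_um)
    return stack, rois


def segment_cells(
    stack: FrameStack,
    min_area_px: int = 20,
) -> list[CellROI]:
    """Segment cells from the time-summed image.

    Otsu global threshold on the summed image, connected components, and a
    minimum-area filter.  Suited to the synthetic fixtures this package
    renders (bright, well-separated disks); real recordings were delineated
    manually.  An empty or featureless stack yields an empty list.
    """
    total = stack.frames.sum(axis=0).astype(float)
    if total.max() == total.min():
        return []
    thresh = skimage.filters.threshold_otsu(total)
    labels = skimage.measure.label(total > thresh)
    rois: list[CellROI] = []
    for region in skimage.measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        rois.append(
            CellROI(
                cell_id=len(rois),
                pixels=region.coords,
                centroid_um=(float(cx * stack.pixel_size_um), float(cy * stack.pixel_size_um)),
            )
        )
    return rois


def extract_cell_traces(
    stack: FrameStack,
    rois: list[CellROI],
) -> tuple[CellTraceSet, np.ndarray]:
    """Mean ROI fluorescence per frame, plus the collective photon sum.

    For each ROI, ``F_i(t_k) = P_i(t_k) / |A_i|`` in photons per pixel per
    sampling interval.  The collective signal is the total photon count per
    frame over the whole field.  Divide by ``stack.dt_s`` to convert either to
    photons/s.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    h, w = stack.shape
    values = np.empty((len(rois), stack.n_frames))
    for i, roi in enumerate(rois):
        if roi.pixels[:, 0].min() < 0 or roi.pixels[:, 0].max() >= h \
                or roi.pixels[:, 1].min() < 0 or roi.pixels[:, 1].max() >= w:
            raise ValueError(f"ROI {roi.cell_id} lies outside the frame bounds")
        values[i] = stack.frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].sum(axis=1) / roi.area_px
    collective = stack.frames.sum(axis=(1, 2))
    traces = CellTraceSet(
        time_s=stack.time_grid(),
        values=values,
        cell_ids=np.array([roi.cell_id for roi in rois]),
        centroids_um=np.array([roi.centroid_um for roi in rois]),
        stage="raw",
    )
    return traces, collective
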