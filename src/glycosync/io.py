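"""File formats: CSV/TSV traces, YAML configs, JSON summaries, TIFF stacks, ROIs.

CSV is the canonical trace format.  Long format has columns
``time_s, cell_id, value``; wide format has ``time_s`` plus one column per
cell (``cell_<id>``); both are auto-detected on read.  Stage and grid metadata
travel as ``#``-prefixed header comments so a written file round-trips
losslessly (to numeric round-off).  Frame stacks are multi-page 16-bit TIFFs
with acquisition metadata in the TIFF description; ROIs serialise to JSON with
run-length-encoded pixel rows or to a 16-bit label-image TIFF.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CellROI, FrameStack
from .popsim import GroundTruth, PopulationConfig
from .traces import CellTraceSet

__all__ = [
    "read_traces",
    "write_traces",
    "load_config",
    "save_config",
    "write_ground_truth",
    "read_ground_truth",
    "write_stack",
    "read_stack",
    "rois_to_json",
    "rois_from_json",
    "write_label_image",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces(traces: CellTraceSet, path: str | Path, format: str = "long") -> None:
    """Write a trace set as CSV with metadata header comments."""
    if format not in ("long", "wide"):
        raise ValueError("format must be 'long' or 'wide'")
    path = Path(path)
    header = [
        "# glycosync traces",
        f"# stage: {traces.stage}",
        f"# dt_s: {traces.dt_s!r}",
    ]
    if traces.centroids_um is not None:
        header.append(f"# centroids_um: {json.dumps(traces.centroids_um.tolist())}")
        header.append(f"# centroid_cell_ids: {json.dumps(np.asarray(traces.cell_ids).tolist())}")
    if format == "long":
        frame = traces.to_long_frame()
    else:
        frame = pd.DataFrame({"time_s": traces.time_s})
        for cid, row in zip(traces.cell_ids, traces.values):
            frame[f"cell_{cid}"] = row
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False)


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_traces(path: str | Path) -> CellTraceSet:
    """Read a long- or wide-format trace CSV/TSV (auto-detected).

    Raises on non-uniform time grids (naming the offending rows) and on
    duplicated (time, cell) pairs.
    """
    path = Path(path)
    meta = _parse_header(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, comment="#", sep=sep)
    stage = meta.get("stage", "raw")

    if "cell_id" in frame.columns:
        value_col = [c for c in frame.columns if c not in ("time_s", "cell_id")]
        if len(value_col) != 1:
            raise ValueError(f"long-format trace file needs exactly one value column, got {value_col}")
        traces = CellTraceSet.from_long_frame(
            frame.rename(columns={value_col[0]: "value"}), stage=stage
        )
    else:
        if "time_s" not in frame.columns:
            raise ValueError("trace file must have a time_s column")
        cell_cols = [c for c in frame.columns if c != "time_s"]
        if not cell_cols:
            raise ValueError("wide-format trace file has no cell columns")
        ids = []
        for c in cell_cols:
            name = c.removeprefix("cell_")
            ids.append(int(name) if name.lstrip("-").isdigit() else name)
        traces = CellTraceSet(
            time_s=frame["time_s"].to_numpy(float),
            values=frame[cell_cols].to_numpy(float).T,
            cell_ids=np.asarray(ids),
            stage=stage,
        )
    if "centroids_um" in meta:
        centroids = np.asarray(json.loads(meta["centroids_um"]), dtype=float)
        order_ids = json.loads(meta.get("centroid_cell_ids", "null"))
        if order_ids is not None:
            lookup = {cid: pos for cid, pos in zip(order_ids, centroids)}
            centroids = np.array([lookup[cid] for cid in traces.cell_ids.tolist()])
        traces.centroids_um = centroids
    return traces


# ---------------------------------------------------------------------------
# configs and ground truth
# ---------------------------------------------------------------------------

def save_config(config: PopulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> PopulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return PopulationConfig.from_dict(data)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "natural_period_s": truth.natural_period_s.tolist(),
        "phase": truth.phase.tolist(),
        "amplitude_envelope": truth.amplitude_envelope.tolist(),
        "onset_s": truth.onset_s.tolist(),
        "offset_s": truth.offset_s.tolist(),
        "coupling": truth.coupling,
        "positions_um": None if truth.positions_um is None else truth.positions_um.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        natural_period_s=np.asarray(d["natural_period_s"], float),
        phase=np.asarray(d["phase"], float),
        amplitude_envelope=np.asarray(d["amplitude_envelope"], float),
        onset_s=np.asarray(d["onset_s"], float),
        offset_s=np.asarray(d["offset_s"], float),
        coupling=float(d["coupling"]),
        positions_um=None if d["positions_um"] is None else np.asarray(d["positions_um"], float),
    )


# ---------------------------------------------------------------------------
# frame stacks and ROIs
# ---------------------------------------------------------------------------

def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack as a multi-page 16-bit TIFF."""
    if stack.frames.max() > np.iinfo(np.uint16).max:
        raise ValueError("photon counts exceed the 16-bit TIFF range")
    description = json.dumps(
        {
            "dt_s": stack.dt_s,
            "pixel_size_um": stack.pixel_size_um,
            "fov_diameter_um": stack.fov_diameter_um,
        }
    )
    tifffile.imwrite(Path(path), stack.frames.astype(np.uint16),
                     photometric="minisblack", description=description)


def read_stack(path: str | Path) -> FrameStack:
    with tifffile.TiffFile(Path(path)) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        pass
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(
        frames=frames.astype(np.int64),
        pixel_size_um=float(meta.get("pixel_size_um", 0.33)),
        dt_s=float(meta.get("dt_s", 2.0)),
        fov_diameter_um=float(meta.get("fov_diameter_um", 169.0)),
    )


def _rle_encode(pixels: np.ndarray) -> list[list[int]]:
    """Run-length encode a pixel set as [row, col_start, length] runs."""
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    px = pixels[order]
    runs: list[list[int]] = []
    for row, col in px:
        if runs and runs[-1][0] == row and runs[-1][1] + runs[-1][2] == col:
            runs[-1][2] += 1
        else:
            runs.append([int(row), int(col), 1])
    return runs


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    pixels = []
    for row, col, length in runs:
        for c in range(col, col + length):
            pixels.append((row, c))
    return np.array(pixels, dtype=int)


def rois_to_json(rois: list[CellROI], path: str | Path) -> None:
    payload = [
        {
            "cell_id": roi.cell_id,
            "centroid_um": list(roi.centroid_um),
            "runs": _rle_encode(roi.pixels),
        }
        for roi in rois
    ]
    Path(path).write_text(json.dumps(payload))


def rois_from_json(path: str | Path) -> list[CellROI]:
    payload = json.loads(Path(path).read_text())
    return [
        CellROI(
            cell_id=int(item["cell_id"]),
            pixels=_rle_decode(item["runs"]),
            centroid_um=tuple(item["centroid_um"]),
        )
        for item in payload
    ]


def write_label_image(
    rois: list[CellROI],
    path: str | Path,
    shape: tuple[int, int] = (512, 512),
) -> None:
    """Label image with cell_id + 1 per ROI pixel (0 = background), 16-bit TIFF."""
    labels = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        labels[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.cell_id + 1
    tifffile.imwrite(Path(path), labels)


# ---------------------------------------------------------------------------
# run provenance
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one CLI invocation, written next to its outputs."""

    subcommand: str
    params: dict
    master_seed: int | None
    version: str
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
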