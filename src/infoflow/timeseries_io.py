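"""Reading image stacks and ROI definitions, extracting per-ROI traces.

A trace is the per-frame arithmetic mean of pixel intensities inside a
fixed, axis-aligned rectangular region of interest (ROI).  Rectangles use
0-based pixel indices and half-open extents: an ROI at (x0, y0) with size
(width, height) covers columns [x0, x0+width) and rows [y0, y0+height).
ROIs are static across frames; cells that move out of their ROI are the
user's problem (pick ROIs that stay within one cell, or discard them).

Trace tables are plain CSV: first column is the frame index, every other
column is one trace, with the column header encoding the ROI label and the
channel as ``label@channel`` (a bare ``label`` means an unnamed channel).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RoiSpec",
    "IntensityTrace",
    "extract_traces",
    "read_stack",
    "read_roi_config",
    "read_trace_table",
    "write_trace_table",
]

DEFAULT_ROI_SIZE = 100  # pixels per side, the conventional ROI extent


@dataclass(frozen=True)
class RoiSpec:
    """An axis-aligned pixel rectangle with a label and a display color."""

    label: str
    x0: int
    y0: int
    width: int = DEFAULT_ROI_SIZE
    height: int = DEFAULT_ROI_SIZE
    color: str = "gray"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("ROI label must be a non-empty string")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI {self.label!r}: offsets must be >= 0")
        if self.width < 1 or self.height < 1:
            raise ValueError(f"ROI {self.label!r}: extents must be >= 1")

    def contains_within(self, n_rows: int, n_cols: int) -> bool:
        return self.x0 + self.width <= n_cols and self.y0 + self.height <= n_rows


@dataclass
class IntensityTrace:
    """One ROI's mean intensity per frame in one channel."""

    roi_label: str
    channel: str
    values: np.ndarray
    frame_interval: float = 60.0  # seconds per frame; metadata only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError(
                f"trace {self.roi_label!r}: need a non-empty 1-D series"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.roi_label!r}: non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def column_name(self) -> str:
        return f"{self.roi_label}@{self.channel}" if self.channel else self.roi_label


def extract_traces(
    stack: np.ndarray,
    rois: Sequence[RoiSpec],
    channel: str = "",
    frame_interval: float = 60.0,
) -> list[IntensityTrace]:
    """Mean-intensity trace of each ROI across all frames of a stack.

    Parameters
    ----------
    stack
        3-D array of shape (frames, rows, cols); any integer or real dtype.
    rois
        Rectangles to average over.  Every rectangle must lie fully inside
        the image plane.
    channel
        Channel name recorded on the returned traces.

    Returns
    -------
    One :class:`IntensityTrace` per ROI, in ROI order.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3-D stack (frames, rows, cols), got {stack.shape}")
    n_frames, n_rows, n_cols = stack.shape
    if n_frames == 0:
        raise ValueError("empty stack: no frames")
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        raise ValueError("ROI labels must be unique within one specimen")
    traces = []
    for roi in rois:
        if not roi.contains_within(n_rows, n_cols):
            raise ValueError(
                f"ROI {roi.label!r} [{roi.x0}:{roi.x0 + roi.width}, "
                f"{roi.y0}:{roi.y0 + roi.height}) exceeds the "
                f"{n_rows}x{n_cols} image plane"
            )
        block = stack[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
        traces.append(
            IntensityTrace(
                roi_label=roi.label,
                channel=channel,
                values=block.astype(float).mean(axis=(1, 2)),
                frame_interval=frame_interval,
            )
        )
    return traces


def read_stack(path: str | Path) -> np.ndarray:
    """Read a grayscale multi-frame TIFF stack as (frames, rows, cols)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {arr.shape}")
    return arr


def read_roi_config(path: str | Path) -> list[RoiSpec]:
    """Read ROI rectangles from a JSON file.

    The file is either a list of objects or ``{"rois": [...]}``; each object
    carries label, x0, y0 and optionally width, height, color.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict):
        doc = doc.get("rois", [])
    return [RoiSpec(**entry) for entry in doc]


def _split_column(name: str) -> tuple[str, str]:
    label, _, channel = name.partition("@")
    return label, channel


def read_trace_table(path: str | Path, frame_interval: float = 60.0) -> list[IntensityTrace]:
    """Read a trace-table CSV (frame index column + one column per trace)."""
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    trace_cols = header[1:]
    dupes = {c for c in trace_cols if trace_cols.count(c) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate column labels {sorted(dupes)}")
    df = pd.read_csv(path)
    traces = []
    for col in df.columns[1:]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna() & df[col].notna()]
        if df[col].isna().any() or len(bad):
            row = int(bad[0]) if len(bad) else int(df[col].index[df[col].isna()][0])
            raise ValueError(
                f"{path}: non-numeric or missing cell at row {row}, column {col!r}"
            )
        label, channel = _split_column(str(col))
        traces.append(
            IntensityTrace(label, channel, numeric.to_numpy(float), frame_interval)
        )
    return traces


def write_trace_table(path: str | Path, traces: Sequence[IntensityTrace]) -> None:
    """Write traces as CSV; inverse of :func:`read_trace_table`."""
    if not traces:
        raise ValueError("no traces to write")
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths {sorted(lengths)}")
    cols = [t.column_name for t in traces]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate (label, channel) pairs among traces")
    df = pd.DataFrame(
        {c: t.values for c, t in zip(cols, traces)},
        index=pd.RangeIndex(lengths.pop(), name="frame"),
    )
    df.to_csv(path)
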