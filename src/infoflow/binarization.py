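"""Thresholding of intensity traces into binary on/off state sequences.

The default threshold is the trace's own arithmetic mean, taken as the
cutoff between signal and noise; median, a fixed user value, and Otsu's
histogram method are offered as alternatives.  Each trace is thresholded
on its own statistic, never on a global per-image level, so ROIs with
different baselines are comparable after binarization.

Tie rule: a value exactly equal to the threshold maps to 0 (inactive).
Strict inequality makes the constant-trace case deterministic — nothing
exceeds its own mean — so a constant trace binarizes to all zeros and is
flagged as degenerate rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries_io import IntensityTrace

__all__ = ["BinaryTrace", "binarize", "active_fraction", "METHODS"]

METHODS = ("mean", "median", "fixed", "otsu")


def _otsu_level(values: np.ndarray) -> float:
    """Exact Otsu level: the inter-class-variance-maximizing split.

    Computed on the trace's empirical value distribution (one histogram
    bin per distinct value) rather than a fixed-width histogram, which
    would misplace boundary values on short traces.  Returns the largest
    value of the low class, so the strict ``>`` rule assigns classes
    exactly as the optimal split does.
    """
    uniq, counts = np.unique(values, return_counts=True)
    w = np.cumsum(counts)  # low-class sizes for split after uniq[i]
    total = w[-1]
    csum = np.cumsum(uniq * counts)
    mean_lo = csum / w
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_hi = (csum[-1] - csum) / (total - w)
    var_between = w * (total - w) * (mean_lo - mean_hi) ** 2
    best = int(np.nanargmax(var_between[:-1]))  # last split leaves hi empty
    return float(uniq[best])


@dataclass
class BinaryTrace:
    """A {0,1} state sequence derived from one intensity trace."""

    roi_label: str
    channel: str
    states: np.ndarray
    threshold_used: float = float("nan")
    method: str = "mean"
    degenerate: bool = False  # constant source trace; all-zero states

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("states must be a non-empty 1-D sequence")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must contain only 0 and 1")

    def __len__(self) -> int:
        return self.states.size

    @property
    def column_name(self) -> str:
        return f"{self.roi_label}@{self.channel}" if self.channel else self.roi_label


def binarize(
    trace: IntensityTrace,
    method: str = "mean",
    fixed_value: float | None = None,
) -> BinaryTrace:
    """Threshold a trace: state 1 where value > threshold, else 0.

    ``method`` selects the threshold: ``mean`` (arithmetic mean of the
    trace), ``median``, ``fixed`` (the supplied ``fixed_value``), or
    ``otsu`` (inter-class-variance-maximizing level on the value
    histogram).  A constant trace under a data-driven method yields
    all-zero states with ``degenerate=True``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if len(trace) < 2:
        raise ValueError(f"trace {trace.roi_label!r}: need >= 2 frames to binarize")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method 'fixed' requires fixed_value")
        threshold = float(fixed_value)
    elif fixed_value is not None:
        raise ValueError("fixed_value is only meaningful with method 'fixed'")
    values = trace.values
    degenerate = False
    if method != "fixed" and np.ptp(values) == 0:
        threshold = float(values[0])
        degenerate = True
    elif method == "mean":
        threshold = float(values.mean())
    elif method == "median":
        threshold = float(np.median(values))
    elif method == "otsu":
        threshold = _otsu_level(values)
    return BinaryTrace(
        roi_label=trace.roi_label,
        channel=trace.channel,
        states=(values > threshold).astype(np.uint8),
        threshold_used=threshold,
        method=method,
        degenerate=degenerate,
    )


def active_fraction(b: BinaryTrace | np.ndarray) -> float:
    """Fraction of frames in the active (1) state."""
    states = b.states if isinstance(b, BinaryTrace) else np.asarray(b)
    if states.size == 0:
        raise ValueError("empty trace")
    return float(np.mean(states))
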