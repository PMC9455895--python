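"""Plug-in discrete information metrics over binary state sequences.

All estimators are maximum-likelihood ("plug-in"): empirical frequencies
are substituted directly into the defining formulas, with no bias
correction.  Plug-in estimates of mutual-information-like quantities are
positively biased at small sample sizes; that bias is absorbed by the
surrogate null of :mod:`infoflow.surrogates` rather than corrected
analytically.  Logarithms are base 2 throughout (values in bits), with the
conventions 0·log2 0 = 0 and empty conditional cells contributing 0.

Metrics pool over every frame index with a complete history window; there
is no circular wrapping, which would fabricate transitions.

Estimator summary, for a binary series x (target) and y (source):

- Shannon information / entropy:   H = −p·log2 p − (1−p)·log2(1−p),
  p the active fraction.
- Mutual information (MI):         I(x_t ; y_t), symmetric, from the 2×2
  empirical joint over simultaneous frames.
- Delayed MI (DMI):                I(x_t ; y_{t+u}) at lag u; detects lagged
  correlation, not causation.
- Active information storage (AIS): I(x_{t−k..t−1} ; x_t) — how well a
  series' own k-frame past predicts its present.
- Transfer entropy (TE):           I(x_{t+1} ; y-past | x-past); directional
  information the source's l-history provides about the target's next
  state beyond the target's own k-history (Schreiber's measure).
- Effective information (EI):      MI between a uniformly imposed
  intervention on a transition model's state and the resulting next-state
  distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binarization import BinaryTrace, active_fraction

__all__ = [
    "MetricParams",
    "MetricResult",
    "TransitionModel",
    "UndersampledEmbeddingWarning",
    "shannon_information",
    "mutual_information",
    "delayed_mutual_information",
    "active_information_storage",
    "transfer_entropy",
    "effective_information",
    "METRIC_NAMES",
]

METRIC_NAMES = ("entropy", "mi", "dmi", "ais", "te", "ei")


class UndersampledEmbeddingWarning(UserWarning):
    """History embedding too long for the series length to sample well."""


@dataclass(frozen=True)
class MetricParams:
    """Embedding and delay parameters shared by the history-based metrics.

    history_k : target/self embedding length for AIS and TE (frames).
    source_l  : source embedding length for TE (frames).
    lag_u     : delay for delayed MI (frames).

    Defaults are k = l = u = 1.  With ~60-frame acquisitions the number of
    history words grows as 2^k, so k > 2 is severely undersampled; longer
    embeddings are allowed but trigger an :class:`UndersampledEmbeddingWarning`.
    """

    history_k: int = 1
    source_l: int = 1
    lag_u: int = 1

    def __post_init__(self) -> None:
        if self.history_k < 1:
            raise ValueError("history_k must be >= 1")
        if self.source_l < 1:
            raise ValueError("source_l must be >= 1")
        if self.lag_u < 0:
            raise ValueError("lag_u must be >= 0")


@dataclass
class MetricResult:
    """One metric value in bits with its parameters and provenance."""

    metric: str
    value_bits: float
    source_label: str
    target_label: str
    channel_pair: tuple[str, str] = ("", "")
    params: MetricParams = MetricParams()
    p_value: float | None = None
    n_surrogates: int | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not np.isfinite(self.value_bits) or self.value_bits < 0:
            raise ValueError(f"value_bits must be finite and >= 0, got {self.value_bits}")

    @property
    def significant(self) -> bool | None:
        return None if self.p_value is None else self.p_value < 0.05


@dataclass
class TransitionModel:
    """Row-stochastic state-transition matrix for effective information.

    Row r is the distribution over next states when the system is forced
    into state r.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("transition matrix must be square")
        if (self.matrix < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1 within 1e-9; got sums {rows}")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def _states(x: BinaryTrace | Sequence[int] | np.ndarray) -> np.ndarray:
    if isinstance(x, BinaryTrace):
        return x.states
    arr = np.asarray(x)
    if arr.dtype != np.uint8:
        arr = arr.astype(np.uint8)
    return arr


def _entropy_bits(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))


def _mi_from_counts(c: np.ndarray) -> float:
    """Plug-in MI in bits from a 2-D joint count table."""
    n = c.sum()
    cx = c.sum(axis=1, keepdims=True)
    cy = c.sum(axis=0, keepdims=True)
    nz = c > 0
    # I = (1/n) sum c * log2(c*n / (cx*cy)); marginals are > 0 wherever c is
    val = float((c[nz] * np.log2(c[nz] * n / (cx * cy)[nz])).sum() / n)
    return max(val, 0.0)


def _word_codes(x: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each length-k window; code[i] encodes x[i..i+k-1]."""
    n = x.size - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = (codes << 1) | x[j : j + n]
    return codes


def _warn_if_undersampled(T: int, n_cells: int) -> None:
    if 3 * n_cells > T:
        warnings.warn(
            f"embedding spans {n_cells} joint states for {T} frames; "
            "plug-in estimates will be strongly biased",
            UndersampledEmbeddingWarning,
            stacklevel=3,
        )


def shannon_information(b: BinaryTrace | np.ndarray) -> float:
    """Entropy of a binary signal in bits: 1 bit at 50% activity, 0 for constant."""
    return _entropy_bits(active_fraction(_states(b)))


def mutual_information(
    x: BinaryTrace | np.ndarray, y: BinaryTrace | np.ndarray
) -> float:
    """Plug-in MI in bits between two equal-length binary series."""
    xs, ys = _states(x), _states(y)
    if xs.size != ys.size:
        raise ValueError(f"length mismatch: {xs.size} vs {ys.size}")
    c = np.bincount(2 * xs.astype(np.int64) + ys, minlength=4).reshape(2, 2)
    return _mi_from_counts(c)


def delayed_mutual_information(
    x: BinaryTrace | np.ndarray, y: BinaryTrace | np.ndarray, lag_u: int = 1
) -> float:
    """MI between x at time t and y at time t + lag_u, pooled over valid t."""
    xs, ys = _states(x), _states(y)
    if xs.size != ys.size:
        raise ValueError(f"length mismatch: {xs.size} vs {ys.size}")
    if lag_u < 0:
        raise ValueError("lag_u must be >= 0")
    if lag_u >= xs.size:
        raise ValueError(f"lag {lag_u} leaves no aligned pairs for length {xs.size}")
    if lag_u == 0:
        return mutual_information(xs, ys)
    return mutual_information(xs[:-lag_u], ys[lag_u:])


def active_information_storage(
    x: BinaryTrace | np.ndarray, history_k: int = 1
) -> float:
    """MI in bits between a series' length-k past window and its present value."""
    xs = _states(x)
    if history_k < 1:
        raise ValueError("history_k must be >= 1")
    T = xs.size
    if T < history_k + 2:
        raise ValueError(f"series of length {T} too short for history_k={history_k}")
    _warn_if_undersampled(T, 2 ** (history_k + 1))
    hist = _word_codes(xs, history_k)[: T - history_k]
    present = xs[history_k:].astype(np.int64)
    c = np.bincount(hist * 2 + present, minlength=2 ** (history_k + 1))
    return _mi_from_counts(c.reshape(-1, 2))


def transfer_entropy(
    source: BinaryTrace | np.ndarray,
    target: BinaryTrace | np.ndarray,
    history_k: int = 1,
    source_l: int = 1,
) -> float:
    """Schreiber transfer entropy source → target, in bits.

    Information the source's length-l history provides about the target's
    next state beyond the target's own length-k history.  Zero for targets
    that are deterministic given their own past.
    """
    ys, xs = _states(source), _states(target)
    if xs.size != ys.size:
        raise ValueError(f"length mismatch: {ys.size} vs {xs.size}")
    if history_k < 1 or source_l < 1:
        raise ValueError("history_k and source_l must be >= 1")
    T = xs.size
    m = max(history_k, source_l)
    if T < m + 2:
        raise ValueError(
            f"series of length {T} too short for k={history_k}, l={source_l}"
        )
    _warn_if_undersampled(T, 2 ** (history_k + source_l + 1))
    K, L = 2**history_k, 2**source_l
    xh = _word_codes(xs, history_k)[m - history_k : T - history_k]
    yh = _word_codes(ys, source_l)[m - source_l : T - source_l]
    x_next = xs[m:].astype(np.int64)
    flat = (x_next * K + xh) * L + yh
    c = np.bincount(flat, minlength=2 * K * L).reshape(2, K, L).astype(float)
    n = c.sum()
    c_hist_pair = c.sum(axis=0)  # (K, L): (target-hist, source-hist)
    c_next_hist = c.sum(axis=2)  # (2, K): (next, target-hist)
    c_hist = c_hist_pair.sum(axis=1)  # (K,)
    nz = c > 0
    num = c * c_hist[None, :, None]
    den = c_hist_pair[None, :, :] * c_next_hist[:, :, None]
    val = float((c[nz] * np.log2(num[nz] / den[nz])).sum() / n)
    return max(val, 0.0)


def effective_information(
    m: TransitionModel | np.ndarray,
    intervention: np.ndarray | None = None,
) -> float:
    """MI between an imposed intervention and the resulting next state.

    Each state r is forced with probability ``intervention[r]`` (uniform by
    default — maximum-entropy noise injection over states) and the model's
    row r gives the next-state distribution; EI is the MI of that joint.
    log2 n bits for a permutation map on n states, 0 for a constant map.
    """
    model = m if isinstance(m, TransitionModel) else TransitionModel(np.asarray(m))
    P = model.matrix
    n = model.n_states
    if intervention is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(intervention, dtype=float)
        if w.shape != (n,) or (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("intervention must be a length-n probability vector")
    p_next = w @ P
    joint = w[:, None] * P
    nz = joint > 0
    denom = (w[:, None] * p_next[None, :])[nz]
    val = float((joint[nz] * np.log2(joint[nz] / denom)).sum())
    return max(val, 0.0)
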