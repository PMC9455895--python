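"""Surrogate-randomization significance and group comparisons.

The null model is whole-series frame permutation: a surrogate trace is the
original with its frame order shuffled by a uniformly random permutation.
This destroys all temporal structure while preserving the marginal state
distribution exactly, so surrogate entropy equals observed entropy for
every replicate and any excess of the observed metric over the surrogate
ensemble reflects temporal/joint structure, not marginal activity.

p-values are one-sided empirical with the +1 (Davison–Hinkley) correction:
p = (1 + #{surrogate >= observed}) / (1 + n).  One-sided because every
metric here is non-negative and only "significantly higher than chance" is
flagged; the minimum attainable p is 1/(n+1), never 0.

Group-level contrasts (e.g. one condition's metric values against
another's) use two-sided Mann–Whitney rank-sum tests, exact for small
groups, tie-corrected normal approximation otherwise.

No multiple-testing correction is applied across table cells; see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binarization import BinaryTrace
from .info_metrics import (
    MetricParams,
    MetricResult,
    active_information_storage,
    delayed_mutual_information,
    mutual_information,
    shannon_information,
    transfer_entropy,
)

__all__ = [
    "SurrogateEnsemble",
    "GroupComparison",
    "SHUFFLE_METHODS",
    "shuffle_surrogate",
    "surrogate_test",
    "rank_sum_compare",
    "pairwise_table",
    "results_to_frame",
]

SHUFFLE_METHODS = ("shuffle_source", "shuffle_target", "shuffle_both", "shuffle_self")

# metric name -> (arity, evaluator on raw uint8 state arrays)
_EVALUATORS = {
    "entropy": (1, lambda x, y, p: shannon_information(x)),
    "ais": (1, lambda x, y, p: active_information_storage(x, p.history_k)),
    "mi": (2, lambda x, y, p: mutual_information(x, y)),
    "dmi": (2, lambda x, y, p: delayed_mutual_information(x, y, p.lag_u)),
    # surrogate_test takes (source, target); transfer_entropy(source, target)
    "te": (2, lambda x, y, p: transfer_entropy(x, y, p.history_k, p.source_l)),
}


@dataclass
class SurrogateEnsemble:
    """Seeded collection of metric values under frame-shuffled nulls."""

    metric: str
    n: int
    seed: int
    method: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n,):
            raise ValueError("ensemble length must equal n")


@dataclass
class GroupComparison:
    """Two-sided Mann–Whitney comparison of two groups of metric values."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    sidedness: str = "two_sided"


def shuffle_surrogate(
    b: BinaryTrace, seed: int | np.random.Generator
) -> BinaryTrace:
    """Frame-order permutation surrogate of one binary trace.

    The multiset of states (hence the active fraction and entropy) is
    preserved exactly; all temporal structure is destroyed.  Passing the
    same seed reproduces the surrogate bit-for-bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return BinaryTrace(
        roi_label=b.roi_label,
        channel=b.channel,
        states=rng.permutation(b.states),
        threshold_used=b.threshold_used,
        method=b.method,
        degenerate=b.degenerate,
    )


def _default_method(metric: str) -> str:
    return "shuffle_self" if _EVALUATORS[metric][0] == 1 else "shuffle_source"


def surrogate_test(
    metric: str,
    source: BinaryTrace,
    target: BinaryTrace | None = None,
    params: MetricParams = MetricParams(),
    n: int = 1000,
    seed: int = 0,
    method: str | None = None,
) -> tuple[MetricResult, SurrogateEnsemble, float]:
    """Observed metric plus its frame-shuffle null ensemble and empirical p.

    For one-trace metrics (entropy, AIS) pass only ``source`` and the
    ``shuffle_self`` method; for pairwise metrics (MI, DMI, TE) ``source``
    and ``target`` with ``shuffle_source``, ``shuffle_target`` or
    ``shuffle_both``.  Each of the ``n`` replicates independently
    re-permutes the designated trace(s).
    """
    if metric not in _EVALUATORS:
        raise ValueError(f"no surrogate test for metric {metric!r}")
    arity, evaluate = _EVALUATORS[metric]
    if method is None:
        method = _default_method(metric)
    if method not in SHUFFLE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {SHUFFLE_METHODS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if arity == 1:
        if target is not None and target is not source:
            raise ValueError(f"metric {metric!r} takes a single trace")
        if method != "shuffle_self":
            raise ValueError(f"metric {metric!r} requires method 'shuffle_self'")
        target = source
    else:
        if target is None:
            raise ValueError(f"metric {metric!r} requires source and target traces")
        if method == "shuffle_self":
            raise ValueError(f"method 'shuffle_self' is for single-trace metrics")

    xs, ys = source.states, target.states
    observed = evaluate(xs, ys, params)
    rng = np.random.default_rng(seed)
    values = np.empty(n)
    shuffle_x = method in ("shuffle_source", "shuffle_both", "shuffle_self")
    shuffle_y = method in ("shuffle_target", "shuffle_both")
    for i in range(n):
        sx = rng.permutation(xs) if shuffle_x else xs
        sy = rng.permutation(ys) if shuffle_y else (sx if arity == 1 else ys)
        values[i] = evaluate(sx, sy, params)
    # >= with a tolerance so exact ties (e.g. all-zero traces) count as null hits
    p = (1 + int(np.sum(values >= observed - 1e-12))) / (1 + n)
    result = MetricResult(
        metric=metric,
        value_bits=observed,
        source_label=source.roi_label,
        target_label=target.roi_label,
        channel_pair=(source.channel, target.channel),
        params=params,
        p_value=p,
        n_surrogates=n,
    )
    ensemble = SurrogateEnsemble(metric=metric, n=n, seed=seed, method=method, values=values)
    return result, ensemble, p


def rank_sum_compare(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two groups of values.

    Exact enumeration of the rank distribution for group sizes up to 8
    (and no ties); tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = a.size <= 8 and b.size <= 8 and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        n_a=a.size,
        n_b=b.size,
    )


def pairwise_table(
    traces: Sequence[BinaryTrace],
    metric: str,
    params: MetricParams = MetricParams(),
    n: int = 1000,
    seed: int = 0,
    method: str | None = None,
    alpha: float = 0.05,
) -> list[MetricResult]:
    """All-pairs metric table with per-cell surrogate p-values.

    MI/DMI tables are computed once per unordered pair; the MI diagonal is
    each trace's information content (its self-MI, i.e. entropy).  TE
    tables contain one directed value per ordered pair, self-cells
    omitted.  AIS/entropy produce one value per trace.  Cell seeds are
    derived deterministically from ``seed`` so regeneration is exact.
    """
    if metric not in _EVALUATORS:
        raise ValueError(f"no pairwise table for metric {metric!r}")
    arity, _ = _EVALUATORS[metric]
    if arity == 2 and len(traces) < 2:
        raise ValueError("pairwise metrics need at least 2 traces")
    ss = np.random.SeedSequence(seed)
    n_traces = len(traces)
    cell_seeds = [int(s) for s in ss.generate_state(n_traces * n_traces)]

    def cell_seed(i: int, j: int) -> int:
        return cell_seeds[i * n_traces + j] % (2**31)

    results: list[MetricResult] = []
    if arity == 1:
        for i, t in enumerate(traces):
            res, _, _ = surrogate_test(
                metric, t, params=params, n=n, seed=cell_seed(i, i), method="shuffle_self"
            )
            results.append(res)
        return results

    if metric in ("mi", "dmi"):
        for i in range(n_traces):
            # diagonal: self-MI = information content of the trace
            res, _, _ = surrogate_test(
                "entropy", traces[i], params=params, n=n,
                seed=cell_seed(i, i), method="shuffle_self",
            )
            results.append(res)
            for j in range(i + 1, n_traces):
                res, _, _ = surrogate_test(
                    metric, traces[i], traces[j], params=params, n=n,
                    seed=cell_seed(i, j), method=method,
                )
                results.append(res)
    else:  # te: full asymmetric, self-cells omitted
        for i in range(n_traces):
            for j in range(n_traces):
                if i == j:
                    continue
                res, _, _ = surrogate_test(
                    metric, traces[i], traces[j], params=params, n=n,
                    seed=cell_seed(i, j), method=method,
                )
                results.append(res)
    return results


def results_to_frame(results: Sequence[MetricResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy DataFrame of metric results: one row per cell."""
    return pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "source": [r.source_label for r in results],
            "target": [r.target_label for r in results],
            "source_channel": [r.channel_pair[0] for r in results],
            "target_channel": [r.channel_pair[1] for r in results],
            "history_k": [r.params.history_k for r in results],
            "source_l": [r.params.source_l for r in results],
            "lag_u": [r.params.lag_u for r in results],
            "value_bits": [r.value_bits for r in results],
            "p_value": [r.p_value for r in results],
            "n_surrogates": [r.n_surrogates for r in results],
            "significant": [
                (r.p_value is not None and r.p_value < alpha) for r in results
            ],
        }
    )
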