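"""Independent brute-force oracles for the discrete information metrics.

Every function here materializes the full joint count table by explicit
Python-level enumeration over frame indices and computes the metric from
first principles with dictionaries and ``math.log2``.  Nothing is shared
with the package implementation; these are the reference the vectorized
estimators are checked against.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import product


def _h(counts: Counter) -> float:
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values() if c > 0)


def entropy_bf(x) -> float:
    return _h(Counter(int(v) for v in x))


def mi_bf(x, y) -> float:
    assert len(x) == len(y)
    joint = Counter((int(a), int(b)) for a, b in zip(x, y))
    mx = Counter(int(a) for a in x)
    my = Counter(int(b) for b in y)
    n = len(x)
    total = 0.0
    for (a, b), c in joint.items():
        total += (c / n) * math.log2((c / n) / ((mx[a] / n) * (my[b] / n)))
    return total


def dmi_bf(x, y, lag: int) -> float:
    pairs = [(x[t], y[t + lag]) for t in range(len(x) - lag)]
    return mi_bf([a for a, _ in pairs], [b for _, b in pairs])


def ais_bf(x, k: int) -> float:
    words = [tuple(int(v) for v in x[t - k : t]) for t in range(k, len(x))]
    present = [int(x[t]) for t in range(k, len(x))]
    joint = Counter(zip(words, present))
    mw = Counter(words)
    mp = Counter(present)
    n = len(words)
    total = 0.0
    for (w, p), c in joint.items():
        total += (c / n) * math.log2((c / n) / ((mw[w] / n) * (mp[p] / n)))
    return total


def te_bf(source, target, k: int, l: int) -> float:
    """Schreiber TE source→target: sum of p * log2 p(x+|xh,yh)/p(x+|xh)."""
    assert len(source) == len(target)
    m = max(k, l)
    triples = []
    for t in range(m - 1, len(target) - 1):
        xh = tuple(int(v) for v in target[t - k + 1 : t + 1])
        yh = tuple(int(v) for v in source[t - l + 1 : t + 1])
        triples.append((int(target[t + 1]), xh, yh))
    n = len(triples)
    c_full = Counter(triples)
    c_hist_pair = Counter((xh, yh) for _, xh, yh in triples)
    c_next_hist = Counter((x1, xh) for x1, xh, _ in triples)
    c_hist = Counter(xh for _, xh, _ in triples)
    total = 0.0
    for (x1, xh, yh), c in c_full.items():
        p_joint = c / n
        p_cond_full = c / c_hist_pair[(xh, yh)]
        p_cond_hist = c_next_hist[(x1, xh)] / c_hist[xh]
        total += p_joint * math.log2(p_cond_full / p_cond_hist)
    return total


def ei_bf(matrix) -> float:
    """EI by explicit enumeration of the (intervention, next-state) joint."""
    n = len(matrix)
    p_next = [sum(matrix[r][s] for r in range(n)) / n for s in range(n)]
    total = 0.0
    for r, s in product(range(n), range(n)):
        p = matrix[r][s] / n
        if p > 0:
            total += p * math.log2(matrix[r][s] / p_next[s])
    return total


def ei_monte_carlo(matrix, n_samples: int, rng) -> float:
    """EI via an interventional sampler: force a uniform state, draw the
    successor from the forced row, and estimate MI from the sampled joint."""
    import numpy as np

    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    rows = rng.integers(0, n, size=n_samples)
    draws = (rng.random(n_samples)[:, None] > np.cumsum(m, axis=1)[rows]).sum(axis=1)
    return mi_bf(rows.tolist(), draws.tolist())
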