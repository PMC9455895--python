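"""Seeded generators of multi-ROI binary/intensity dynamics.

These generators emulate the study conditions of a two-channel calcium /
actin time-lapse experiment — 9 ROIs per specimen, 60 frames at one frame
per minute — in each qualitative dynamical regime the estimators must
distinguish:

- ``iid``             independent Bernoulli activity (the null regime);
- ``oscillator``      periodic square waves with random phases and flip
                      noise (high self-predictability; two in-phase
                      oscillators are the classic delayed-correlation
                      false positive);
- ``coupled_chain``   a lag-1 copy chain with tunable fidelity (genuine
                      directed information flow);
- ``common_driver``   two ROIs slaved to a hidden shared driver (high MI,
                      zero transfer);
- ``bleaching``       independent noise on a shared monotone exponential
                      decay (the photobleaching artifact: spurious MI
                      after mean-threshold binarization);
- ``two_channel_model`` an invented two-channel mechanism in which a slow,
                      persistent "actin-like" channel gates lag-1 coupling
                      in a fast "calcium-like" channel and drives it
                      within each ROI.  It is a validation model for the
                      estimator suite, not a fitted biophysical model.

Every generator is a pure function of its configuration (including the
seed): the same ``SimConfig`` always reproduces the same traces.
Binary regimes return :class:`~infoflow.binarization.BinaryTrace` lists;
``bleaching`` returns raw :class:`~infoflow.timeseries_io.IntensityTrace`
objects for the full binarize-then-test path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binarization import BinaryTrace
from .timeseries_io import IntensityTrace

__all__ = [
    "SimConfig",
    "REGIMES",
    "gen_iid",
    "gen_oscillator",
    "gen_coupled_chain",
    "gen_common_driver",
    "gen_bleaching",
    "gen_two_channel_model",
    "generate",
    "traces_to_stack",
]

REGIMES = (
    "iid",
    "oscillator",
    "coupled_chain",
    "common_driver",
    "bleaching",
    "two_channel_model",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic specimen.

    Defaults follow the emulated acquisition: 9 ROIs, 60 frames.
    ``coupling_eps`` is copy fidelity in the chain regime (1 = perfect
    copy, 0 = no coupling); ``noise_p`` is a symmetric per-frame bit-flip
    probability; ``drift_rate`` the per-frame exponential bleaching rate.
    The ``a_*``/``b_*`` fields parameterize the two-channel model: channel
    A is a persistent Markov chain (stay-active probability ``a_stay``,
    activation probability ``a_gain``), channel B copies its ring
    neighbour with probability ``b_couple`` when the ROI's A state is
    active, and tracks its own ROI's A state with probability ``a_drive``.
    """

    n_rois: int = 9
    T: int = 60
    seed: int = 0
    regime: str = "iid"
    active_p: float = 0.5
    coupling_eps: float = 0.8
    period: int = 2
    drift_rate: float = 0.05
    noise_p: float = 0.0
    # two-channel model mechanism
    a_stay: float = 0.95
    a_gain: float = 0.15
    a_drive: float = 0.45
    b_couple: float = 0.9
    # bleaching regime intensity scale
    bleach_amplitude: float = 100.0
    bleach_noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.n_rois < 1 or self.T < 2:
            raise ValueError("need n_rois >= 1 and T >= 2")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.coupling_eps <= 1.0:
            raise ValueError("coupling_eps must be in [0, 1]")
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be >= 0")
        if not 0.0 <= self.noise_p <= 0.5:
            raise ValueError("noise_p must be in [0, 0.5]")
        if not 0.0 < self.active_p < 1.0:
            raise ValueError("active_p must be in (0, 1)")


def _binary(states: np.ndarray, label: str, channel: str = "") -> BinaryTrace:
    return BinaryTrace(roi_label=label, channel=channel, states=states, method="fixed")


def _flip(states: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if p <= 0:
        return states
    return np.where(rng.random(states.shape) < p, 1 - states, states).astype(np.uint8)


def gen_iid(cfg: SimConfig) -> list[BinaryTrace]:
    """Independent Bernoulli(active_p) state sequences, one per ROI."""
    rng = np.random.default_rng(cfg.seed)
    return [
        _binary(
            (rng.random(cfg.T) < cfg.active_p).astype(np.uint8), f"roi{i + 1}"
        )
        for i in range(cfg.n_rois)
    ]


def gen_oscillator(
    cfg: SimConfig, phases: Sequence[int] | None = None
) -> list[BinaryTrace]:
    """Square waves of the configured period with per-frame flip noise.

    Each ROI gets an independent uniformly random phase unless ``phases``
    supplies one offset per ROI (e.g. all zeros for in-phase oscillators).
    """
    rng = np.random.default_rng(cfg.seed)
    if phases is None:
        phases = rng.integers(0, cfg.period, size=cfg.n_rois)
    elif len(phases) != cfg.n_rois:
        raise ValueError("need one phase per ROI")
    t = np.arange(cfg.T)
    half = cfg.period / 2
    traces = []
    for i, phase in enumerate(phases):
        wave = (((t + int(phase)) % cfg.period) < half).astype(np.uint8)
        traces.append(_binary(_flip(wave, cfg.noise_p, rng), f"roi{i + 1}"))
    return traces


def gen_coupled_chain(cfg: SimConfig) -> list[BinaryTrace]:
    """Lag-1 copy chain: ROI j+1 copies ROI j one frame later.

    ROI 1 is i.i.d. Bernoulli(0.5); each downstream ROI copies its
    upstream neighbour's previous state, corrupted by an independent flip
    with probability (1 − coupling_eps)/2.  At coupling_eps = 1 the copy
    is perfect; at 0 the chain degenerates to independent noise.
    """
    rng = np.random.default_rng(cfg.seed)
    flip_p = (1.0 - cfg.coupling_eps) / 2.0
    states = np.empty((cfg.n_rois, cfg.T), dtype=np.uint8)
    states[0] = (rng.random(cfg.T) < 0.5).astype(np.uint8)
    for j in range(1, cfg.n_rois):
        copied = np.empty(cfg.T, dtype=np.uint8)
        copied[0] = rng.integers(0, 2)
        copied[1:] = states[j - 1, :-1]
        states[j] = _flip(copied, flip_p, rng)
    return [_binary(states[j], f"roi{j + 1}") for j in range(cfg.n_rois)]


def gen_common_driver(cfg: SimConfig) -> list[BinaryTrace]:
    """Two ROIs slaved to a hidden, maximum-entropy random driver.

    The driver is a uniformly random arrangement of an equal number of
    active and inactive frames (a balanced, memoryless sequence, so its
    empirical entropy is exactly 1 bit for even T).  Both observed ROIs
    copy it at the same lag with independent flip noise ``noise_p``; the
    driver itself is not emitted.  With zero noise the pair shows 1 bit of
    MI yet zero transfer entropy in either direction — correlation without
    direct causation.
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.zeros(cfg.T, dtype=np.uint8)
    base[: cfg.T // 2] = 1
    driver = rng.permutation(base)
    return [
        _binary(_flip(driver, cfg.noise_p, rng), f"roi{i + 1}") for i in range(2)
    ]


def gen_bleaching(cfg: SimConfig) -> list[IntensityTrace]:
    """Independent noise traces on a shared monotone exponential decay.

    Intensity of ROI i at frame t is A·exp(−drift_rate·t) plus i.i.d.
    Gaussian noise.  With strong shared decay, mean-threshold binarization
    turns every trace into nearly the same step function, producing high
    pairwise MI that reflects the bleaching artifact, not coupling.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.T)
    decay = cfg.bleach_amplitude * np.exp(-cfg.drift_rate * t)
    traces = []
    for i in range(cfg.n_rois):
        noise = rng.normal(0.0, cfg.bleach_noise_sigma, size=cfg.T)
        traces.append(
            IntensityTrace(f"roi{i + 1}", "", np.clip(decay + noise, 0.0, None))
        )
    return traces


def gen_two_channel_model(
    cfg: SimConfig,
) -> dict[str, list[BinaryTrace] | dict]:
    """Two coupled channels: a persistent gate channel and a gated fast channel.

    Channel A ("actin-like"): per-ROI two-state Markov chains,
    P(active → active) = ``a_stay``, P(inactive → active) = ``a_gain``,
    mutually independent across ROIs — slow, persistent pulsing with high
    active information storage and no inter-ROI transfer.

    Channel B ("calcium-like"), per ROI j at each frame:

    1. with probability ``a_drive``        → copy the ROI's own A state
       (within-ROI A→B drive);
    2. else with probability ``b_couple`` × A_j(t) → copy ring-neighbour
       B_{j−1}(t) (inter-ROI coupling, gated by the A state);
    3. else                                → fresh Bernoulli(0.5).

    Returns ``{"actin": [...], "calcium": [...], "truth": {...}}`` where
    ``truth`` records the generative couplings (A→B within ROI; B ring
    coupling gated by A; no B→A influence, no inter-ROI A coupling).
    """
    rng = np.random.default_rng(cfg.seed)
    R, T = cfg.n_rois, cfg.T
    # stationary start for the A chains
    p1 = cfg.a_gain / (cfg.a_gain + (1.0 - cfg.a_stay))
    A = np.empty((R, T), dtype=np.uint8)
    B = np.empty((R, T), dtype=np.uint8)
    A[:, 0] = rng.random(R) < p1
    B[:, 0] = rng.random(R) < 0.5
    for t in range(1, T):
        p_active = np.where(A[:, t - 1] == 1, cfg.a_stay, cfg.a_gain)
        A[:, t] = rng.random(R) < p_active
        u_drive = rng.random(R)
        u_couple = rng.random(R)
        fresh = (rng.random(R) < 0.5).astype(np.uint8)
        neighbour = B[np.arange(R) - 1, t - 1]  # ring: ROI 0's neighbour is ROI R-1
        gate_open = u_couple < cfg.b_couple * A[:, t - 1]
        B[:, t] = np.where(
            u_drive < cfg.a_drive,
            A[:, t - 1],
            np.where(gate_open, neighbour, fresh),
        )
    return {
        "actin": [_binary(A[j], f"roi{j + 1}", "actin") for j in range(R)],
        "calcium": [_binary(B[j], f"roi{j + 1}", "calcium") for j in range(R)],
        "truth": {
            "within_roi_drive": "actin->calcium",
            "inter_roi_coupling": "calcium ring lag-1, gated by actin state",
            "a_stationary_active_p": p1,
            "a_stay": cfg.a_stay,
            "a_gain": cfg.a_gain,
            "a_drive": cfg.a_drive,
            "b_couple": cfg.b_couple,
        },
    }


def generate(cfg: SimConfig, **kwargs):
    """Dispatch to the generator named by ``cfg.regime``."""
    return {
        "iid": gen_iid,
        "oscillator": gen_oscillator,
        "coupled_chain": gen_coupled_chain,
        "common_driver": gen_common_driver,
        "bleaching": gen_bleaching,
        "two_channel_model": gen_two_channel_model,
    }[cfg.regime](cfg, **kwargs)


def traces_to_stack(
    traces: Sequence[IntensityTrace | BinaryTrace],
    roi_size: int = 10,
    gap: int = 2,
) -> tuple[np.ndarray, list]:
    """Render traces into a synthetic TIFF-able stack of constant-intensity blocks.

    Each trace becomes one square block laid out on a horizontal strip,
    with its per-frame value painted uniformly across the block.  Returns
    the (frames, rows, cols) array and the matching ROI rectangles, so the
    full image → trace-extraction path can be exercised end to end.
    """
    from .timeseries_io import RoiSpec

    if not traces:
        raise ValueError("no traces to render")
    values = [
        t.values if isinstance(t, IntensityTrace) else t.states.astype(float)
        for t in traces
    ]
    T = len(values[0])
    rows = roi_size + 2 * gap
    cols = len(traces) * (roi_size + gap) + gap
    stack = np.zeros((T, rows, cols), dtype=float)
    rois = []
    for i, (trace, vals) in enumerate(zip(traces, values)):
        x0 = gap + i * (roi_size + gap)
        stack[:, gap : gap + roi_size, x0 : x0 + roi_size] = vals[:, None, None]
        rois.append(
            RoiSpec(label=trace.roi_label, x0=x0, y0=gap, width=roi_size, height=roi_size)
        )
    return stack, rois
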