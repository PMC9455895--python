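"""End-to-end pipeline: extract → binarize → metrics → surrogate tests → tables.

A run is fully described by a :class:`RunConfig` (loadable from YAML or
JSON).  Outputs are tidy CSVs plus a manifest recording every parameter
and the seed, which is sufficient to re-run the pipeline to byte-identical
result files.  Intermediate artifacts (raw and binarized traces) are
persisted for audit; no stage mutates its inputs.

No multiplicity correction is applied across table cells — every cell is
flagged at the configured alpha on its own surrogate p-value.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binarization import BinaryTrace, binarize
from .info_metrics import MetricParams, MetricResult
from .surrogates import pairwise_table, results_to_frame
from .timeseries_io import (
    IntensityTrace,
    extract_traces,
    read_roi_config,
    read_stack,
    read_trace_table,
    write_trace_table,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "render_table"]

logger = logging.getLogger("infoflow")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    ``channels`` maps channel name → input path; each path is either a
    multi-frame TIFF stack (requires ``roi_config``) or a trace-table CSV.
    """

    channels: dict[str, str]
    roi_config: str | None = None
    binarize_method: str = "mean"
    fixed_value: float | None = None
    metrics: list[str] = field(default_factory=lambda: ["ais", "mi", "te"])
    history_k: int = 1
    source_l: int = 1
    lag_u: int = 1
    n_surrogates: int = 1000
    seed: int = 0
    alpha: float = 0.05
    output_dir: str = "infoflow_out"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one input channel is required")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")

    @property
    def params(self) -> MetricParams:
        return MetricParams(self.history_k, self.source_l, self.lag_u)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls(**doc)


@dataclass
class RunResult:
    config: RunConfig
    traces: dict[str, list[IntensityTrace]]
    binarized: dict[str, list[BinaryTrace]]
    results: list[MetricResult]
    frame: pd.DataFrame
    output_dir: Path


def _load_channel(cfg: RunConfig, channel: str, path: str) -> list[IntensityTrace]:
    if path.lower().endswith((".tif", ".tiff")):
        if cfg.roi_config is None:
            raise ValueError(
                f"channel {channel!r}: TIFF input requires an ROI config file"
            )
        stack = read_stack(path)
        rois = read_roi_config(cfg.roi_config)
        return extract_traces(stack, rois, channel=channel)
    traces = read_trace_table(path)
    for t in traces:
        t.channel = t.channel or channel
    return traces


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis described by ``cfg``.

    Deterministic given the config: per-table seeds are derived from
    ``cfg.seed`` and the metric name, so re-running writes byte-identical
    CSVs.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        t0 = time.perf_counter()
        traces: dict[str, list[IntensityTrace]] = {}
        for channel, path in sorted(cfg.channels.items()):
            try:
                traces[channel] = _load_channel(cfg, channel, path)
            except Exception as exc:
                raise RuntimeError(f"stage extract, channel {channel!r}: {exc}") from exc
            logger.info(
                "extract: channel=%s traces=%d frames=%d",
                channel, len(traces[channel]), len(traces[channel][0]),
            )
        lengths = {len(t) for ch in traces.values() for t in ch}
        if len(lengths) > 1:
            raise RuntimeError(
                f"stage extract: channels have unequal frame counts {sorted(lengths)}"
            )

        binarized: dict[str, list[BinaryTrace]] = {}
        for channel, ts in traces.items():
            binarized[channel] = [
                binarize(t, cfg.binarize_method, cfg.fixed_value) for t in ts
            ]
            n_degenerate = sum(b.degenerate for b in binarized[channel])
            if n_degenerate:
                logger.warning(
                    "binarize: channel=%s degenerate_traces=%d", channel, n_degenerate
                )
            write_trace_table(
                out / f"traces_{channel}.csv", ts
            )
            pd.DataFrame(
                {b.column_name: b.states for b in binarized[channel]},
                index=pd.RangeIndex(len(ts[0]), name="frame"),
            ).to_csv(out / f"binarized_{channel}.csv")
            pd.DataFrame(
                {
                    "trace": [b.column_name for b in binarized[channel]],
                    "threshold": [b.threshold_used for b in binarized[channel]],
                    "method": [b.method for b in binarized[channel]],
                    "degenerate": [b.degenerate for b in binarized[channel]],
                }
            ).to_csv(out / f"thresholds_{channel}.csv", index=False)
        logger.info("binarize: method=%s", cfg.binarize_method)

        all_results: list[MetricResult] = []
        for metric_idx, metric in enumerate(cfg.metrics):
            for chan_idx, (channel, bts) in enumerate(sorted(binarized.items())):
                metric_seed = int(
                    np.random.SeedSequence(
                        (cfg.seed, metric_idx, chan_idx)
                    ).generate_state(1)[0] % (2**31)
                )
                try:
                    cells = pairwise_table(
                        bts, metric, cfg.params, n=cfg.n_surrogates,
                        seed=metric_seed, alpha=cfg.alpha,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"stage metrics, metric {metric!r}, channel {channel!r}: {exc}"
                    ) from exc
                all_results.extend(cells)
                logger.info(
                    "metric: metric=%s channel=%s cells=%d significant=%d",
                    metric, channel, len(cells),
                    sum(1 for r in cells if r.p_value is not None and r.p_value < cfg.alpha),
                )

        frame = results_to_frame(all_results, alpha=cfg.alpha)
        frame.to_csv(out / "results.csv", index=False)
        with open(out / "tables.txt", "w") as fh:
            for metric in cfg.metrics:
                for channel in sorted(binarized):
                    sub = [
                        r for r in all_results
                        if (r.metric == metric or (metric in ("mi", "dmi") and r.metric == "entropy"))
                        and r.channel_pair[0] == binarized[channel][0].channel
                    ]
                    if sub:
                        fh.write(f"== {metric} [{channel}] ==\n")
                        fh.write(render_table(sub, alpha=cfg.alpha))
                        fh.write("\n")
        manifest = {
            "package": "infoflow",
            "version": __version__,
            "config": asdict(cfg),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("done: cells=%d elapsed_s=%.2f", len(all_results), time.perf_counter() - t0)
        return RunResult(cfg, traces, binarized, all_results, frame, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def render_table(
    results: Sequence[MetricResult], alpha: float = 0.05
) -> str:
    """Matrix layout of one metric table: sources as rows, targets as columns.

    Cells significant at ``alpha`` are marked with ``*``; on an MI table
    the diagonal holds each trace's information content (its self-MI).
    """
    if not results:
        raise ValueError("no results to render")
    labels = sorted(
        {r.source_label for r in results} | {r.target_label for r in results}
    )
    cells: dict[tuple[str, str], str] = {}
    symmetric = any(r.metric in ("mi", "dmi") for r in results)
    for r in results:
        mark = "*" if (r.p_value is not None and r.p_value < alpha) else " "
        text = f"{r.value_bits:6.3f}{mark}"
        cells[(r.source_label, r.target_label)] = text
        if r.metric in ("mi", "dmi") and r.source_label != r.target_label:
            cells[(r.target_label, r.source_label)] = text
    width = max(7, max(len(l) for l in labels) + 1)
    header = " " * width + "".join(f"{l:>{width}}" for l in labels)
    lines = [header]
    for src in labels:
        row = f"{src:>{width}}"
        for tgt in labels:
            row += f"{cells.get((src, tgt), '      .'):>{width}}"
        lines.append(row)
    if symmetric:
        lines.append("(diagonal: information content; * p < %g)" % alpha)
    else:
        lines.append("(* p < %g)" % alpha)
    return "\n".join(lines) + "\n"
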