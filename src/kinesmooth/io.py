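"""CSV/YAML/JSON input and report output.

Time-series CSV layout: header row; first column is time in seconds,
remaining columns are signal channels. Units are declared in the analysis
config, never inferred from the file. Events CSV: one column of boundary
times in seconds, optional second column with labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (
    Segmentation,
    SmoothnessResult,
    analyze_movement,
    events_to_segmentation,
)
from .errors import FormatError, ParameterError, SamplingError
from .measures import MeasureParams
from .profiles import SampledSignal

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = __version__
JITTER_TOLERANCE = 0.01  # fraction of the median sampling interval

SIGNAL_KINDS = ("position", "accelerometer", "force", "speed")

__all__ = [
    "AnalysisConfig",
    "read_timeseries",
    "read_events",
    "run_analysis",
    "write_report",
    "read_report",
    "result_to_dict",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one smoothness analysis needs, file paths included."""

    input_path: str
    signal_kind: str = "position"
    measure: str = "sparc"
    params: MeasureParams = field(default_factory=MeasureParams)
    events_path: str | None = None
    weight_scheme: str = "uniform"
    task_label: str = ""
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise ParameterError(
                f"signal_kind must be one of {SIGNAL_KINDS}, got {self.signal_kind!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        params = MeasureParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_timeseries(path: str | Path, expected_fs: float | None = None) -> SampledSignal:
    """Read a time-series CSV into a uniformly sampled signal.

    The time column must be strictly increasing. Timing jitter up to 1% of
    the median interval is tolerated: the signal is resampled onto a uniform
    grid by linear interpolation (with a warning). Larger jitter is an
    error rather than silently hidden, since irregular sampling distorts
    derivative- and spectrum-based smoothness estimates.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one channel")
    if df.shape[0] < 4:
        raise FormatError(f"{path}: need at least 4 rows")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    intervals = np.diff(t)
    dt = float(np.median(intervals))
    if expected_fs is not None:
        dt = 1.0 / expected_fs
    jitter = np.max(np.abs(intervals - dt))
    channels = tuple(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if jitter > JITTER_TOLERANCE * dt:
        raise SamplingError(
            f"{path}: timing jitter {jitter:.3g}s exceeds {JITTER_TOLERANCE:.0%} of dt={dt:.3g}s"
        )
    if jitter > 1e-9 * dt:
        logger.warning(
            "%s: %.2g%% timing jitter; resampling onto a uniform %g s grid",
            path, 100 * jitter / dt, dt,
        )
        grid = t[0] + dt * np.arange(int(np.floor((t[-1] - t[0]) / dt)) + 1)
        values = np.column_stack([np.interp(grid, t, values[:, j]) for j in range(values.shape[1])])
    return SampledSignal(float(t[0]), dt, channels, values)


def read_events(path: str | Path) -> tuple[list[float], list[str] | None]:
    """Read an events CSV: boundary times, optional labels."""
    df = pd.read_csv(path)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: events file is empty")
    times = df.iloc[:, 0].to_numpy(dtype=float).tolist()
    labels = df.iloc[:, 1].astype(str).tolist() if df.shape[1] >= 2 else None
    return times, labels


def run_analysis(config: AnalysisConfig) -> SmoothnessResult:
    """Full pipeline: read, transform, segment, measure, aggregate.

    Deterministic: identical input files and config give an identical
    result. With no events file the whole recording is one component.
    """
    sig = read_timeseries(config.input_path)
    if config.events_path:
        events, _labels = read_events(config.events_path)
        seg = events_to_segmentation(events, (sig.start_time, sig.end_time), sig.dt)
    else:
        seg = Segmentation((sig.start_time, sig.end_time))
    result = analyze_movement(
        sig,
        seg,
        measure=config.measure,
        params=config.params,
        weight_scheme=config.weight_scheme,
        signal_kind=config.signal_kind,
        task_label=config.task_label,
    )
    if config.output_path:
        write_report(result, config.output_path, config)
    return result


def result_to_dict(result: SmoothnessResult, config: AnalysisConfig | None = None) -> dict:
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "measure": result.measure,
        "task_label": result.task_label,
        "params": asdict(result.params),
        "overall": result.overall,
        "components": [
            {
                "index": c.index,
                "span": list(c.span),
                "weight": c.weight,
                "value": c.value,
                "label": c.label,
                "error": c.error,
            }
            for c in result.components
        ],
    }
    if config is not None:
        report["config_hash"] = config.content_hash()
    return report


def write_report(
    result: SmoothnessResult, path: str | Path, config: AnalysisConfig | None = None
) -> None:
    """Write a JSON report; numbers round-trip at full precision."""
    with open(path, "w") as fh:
        json.dump(result_to_dict(result, config), fh, indent=2)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
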