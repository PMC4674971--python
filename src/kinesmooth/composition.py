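"""Event-based segmentation and overall smoothness of long movements.

A smoothness measure applied to an entire rhythmic movement conflates the
intermittency of the individual strokes with their temporal organisation
(movement time vs dwell time, number of repetitions). The remedy is to
partition the recording at analyst-chosen event times into non-overlapping
components, estimate smoothness per component, and combine the component
values lambda_i with a weighted average

    Lambda = sum(w_i * lambda_i) / sum(w_i),   sum(w_i) != 0,  w_i >= 0.

The weighted average satisfies the three properties an overall-smoothness
aggregate needs: identical components give Lambda equal to the common value;
Lambda is invariant to re-ordering components; and Lambda lies between the
least and most smooth weighted component.

No canonical segmentation exists — the choice of boundaries is the
analyst's, guided by task events. This module never auto-selects one
silently; ``detect_dwell_boundaries`` is an optional convenience helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    InvalidWeightsError,
    ParameterError,
    RangeError,
    SegmentationError,
)
from .measures import MeasureParams, compute_measure
from .profiles import (
    SampledSignal,
    SpeedProfile,
    accel_magnitude_profile,
    derivative_magnitude,
    speed_from_position,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Segmentation",
    "ComponentResult",
    "SmoothnessResult",
    "segment",
    "events_to_segmentation",
    "overall_smoothness",
    "make_weights",
    "analyze_movement",
    "detect_dwell_boundaries",
    "profile_for_measure",
]


@dataclass(frozen=True)
class Segmentation:
    """Ordered boundary times t_1 < ... < t_{N+1} defining N components.

    Component i covers the half-open window [t_i, t_{i+1}), so the
    components tile [t_1, t_{N+1}) with no sample shared or dropped.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        b = tuple(float(t) for t in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if len(b) < 2:
            raise SegmentationError("need at least two boundaries")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise SegmentationError(f"boundaries must be strictly increasing: {b}")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != self.n_components:
                raise SegmentationError(
                    f"{len(labels)} labels for {self.n_components} components"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def n_components(self) -> int:
        return len(self.boundaries) - 1

    @property
    def spans(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(self.n_components)]


@dataclass(frozen=True)
class ComponentResult:
    """Per-component outcome: a smoothness value or a recorded error."""

    index: int
    span: tuple[float, float]
    weight: float
    value: float | None
    label: str | None = None
    error: str | None = None


@dataclass(frozen=True)
class SmoothnessResult:
    """Overall smoothness Lambda with its per-component breakdown."""

    measure: str
    components: tuple[ComponentResult, ...]
    overall: float | None
    task_label: str = ""
    params: MeasureParams = field(default_factory=MeasureParams)

    @property
    def lambdas(self) -> list[float | None]:
        return [c.value for c in self.components]

    @property
    def weights(self) -> list[float]:
        return [c.weight for c in self.components]


def segment(x: SampledSignal, seg: Segmentation) -> list[SampledSignal]:
    """Cut a signal at the segmentation boundaries.

    Each component takes the samples with t_i <= t < t_{i+1}; the final
    component also receives a sample landing exactly on t_{N+1}, so
    concatenating the components reproduces the signal sample-for-sample.
    """
    t0, t_end = x.start_time, x.end_time
    eps = x.dt * 1e-6
    if seg.boundaries[0] < t0 - eps or seg.boundaries[-1] > t_end + x.dt / 2:
        raise RangeError(
            f"segmentation [{seg.boundaries[0]}, {seg.boundaries[-1]}] outside "
            f"signal span [{t0}, {t_end}]"
        )
    out: list[SampledSignal] = []
    n = x.n_samples
    for i, (ta, tb) in enumerate(seg.spans):
        # 1e-6-sample slack absorbs float error in boundary/dt divisions
        lo = int(np.ceil((ta - t0) / x.dt - 1e-6))
        hi = int(np.ceil((tb - t0) / x.dt - 1e-6))
        if i == seg.n_components - 1:
            hi = max(hi, min(n, int(np.floor((tb - t0) / x.dt + 1e-6)) + 1))
        lo, hi = max(lo, 0), min(hi, n)
        if hi - lo < 4:
            raise SegmentationError(
                f"component {i} spanning [{ta}, {tb}] has only {hi - lo} samples"
            )
        out.append(
            SampledSignal(t0 + lo * x.dt, x.dt, x.channels, x.values[lo:hi], x.units)
        )
    return out


def events_to_segmentation(
    event_times: Sequence[float],
    span: tuple[float, float],
    dt: float = 0.0,
    labels: Sequence[str] | None = None,
) -> Segmentation:
    """Build a segmentation from interior event times plus the span ends.

    Events closer than dt/2 to each other or to a span end are merged (a
    warning is logged), since distinct boundaries within half a sample
    cannot separate any samples.
    """
    t_s, t_e = span
    if not t_e > t_s:
        raise RangeError(f"empty span [{t_s}, {t_e}]")
    events = sorted(float(t) for t in event_times)
    if events and (events[0] < t_s or events[-1] > t_e):
        raise RangeError("event times must lie inside the movement span")
    tol = dt / 2.0
    boundaries = [t_s]
    for t in events:
        if t - boundaries[-1] <= tol or t_e - t <= tol:
            logger.warning("merging event at %g s: within dt/2 of an existing boundary", t)
            continue
        boundaries.append(t)
    boundaries.append(t_e)
    return Segmentation(tuple(boundaries), tuple(labels) if labels is not None else None)


def overall_smoothness(lambdas: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted average of per-component smoothness values."""
    lam = np.asarray(lambdas, dtype=float)
    w = np.asarray(weights, dtype=float)
    if lam.shape != w.shape or lam.ndim != 1:
        raise ParameterError("lambdas and weights must be 1-D of equal length")
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise InvalidWeightsError("weights sum to zero; overall smoothness undefined")
    return float(np.dot(w, lam) / total)


def make_weights(scheme: str | Sequence[float], seg: Segmentation) -> np.ndarray:
    """Weight vector for a segmentation.

    Schemes: ``uniform`` (default), ``odd-only`` / ``even-only`` (1-based
    component index — odd-only keeps components 1, 3, 5, ..., e.g. only the
    outbound strokes of a back-and-forth task), ``duration`` (weight
    proportional to component duration), or an explicit vector.
    """
    n = seg.n_components
    if isinstance(scheme, str):
        if scheme == "uniform":
            return np.ones(n)
        if scheme == "odd-only":
            return np.array([1.0 if (i + 1) % 2 == 1 else 0.0 for i in range(n)])
        if scheme == "even-only":
            return np.array([1.0 if (i + 1) % 2 == 0 else 0.0 for i in range(n)])
        if scheme == "duration":
            return np.array([tb - ta for ta, tb in seg.spans])
        raise ParameterError(f"unknown weight scheme {scheme!r}")
    w = np.asarray(list(scheme), dtype=float)
    if w.size != n:
        raise ParameterError(f"{w.size} weights for {n} components")
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    return w


_TRANSFORMS: dict[str, Callable[[SampledSignal, str], SpeedProfile]] = {}


def profile_for_measure(x: SampledSignal, kind: str, measure: str) -> SpeedProfile:
    """Apply the preprocessing transform a signal kind needs for a measure.

    kind: 'position', 'accelerometer', 'force' (also torque) or 'speed'
    (already a profile; first channel taken).
    """
    jerk_based = measure.lower() in ("dlj", "ldlj")
    if kind == "speed":
        return SpeedProfile(x.start_time, x.dt, x.values[:, 0])
    if kind == "position":
        return speed_from_position(x)
    if kind == "accelerometer":
        # spectral measures: gravity-subtracted magnitude; jerk measures:
        # jerk magnitude straight from the accelerometer
        return derivative_magnitude(x, 1) if jerk_based else accel_magnitude_profile(x)
    if kind == "force":
        return derivative_magnitude(x, 3 if jerk_based else 1)
    raise ParameterError(f"unknown signal kind {kind!r}")


def analyze_movement(
    x: SampledSignal,
    seg: Segmentation,
    measure: str = "sparc",
    params: MeasureParams = MeasureParams(),
    weight_scheme: str | Sequence[float] = "uniform",
    signal_kind: str = "position",
    task_label: str = "",
) -> SmoothnessResult:
    """Segment a movement, score each component, and aggregate.

    Every component is scored and reported, including zero-weight ones
    (smoothness can be tracked event by event). A degenerate component — a
    pure dwell with no movement — is recorded as a per-component error; the
    overall value is computed only if every *weighted* component succeeded.
    """
    pieces = segment(x, seg)
    weights = make_weights(weight_scheme, seg)
    comps: list[ComponentResult] = []
    for i, (piece, w) in enumerate(zip(pieces, weights)):
        label = seg.labels[i] if seg.labels is not None else None
        span = seg.spans[i]
        try:
            v = profile_for_measure(piece, signal_kind, measure)
            value = compute_measure(measure, v, params)
        except DegenerateInputError as exc:
            comps.append(ComponentResult(i, span, float(w), None, label, str(exc)))
            continue
        comps.append(ComponentResult(i, span, float(w), value, label))

    weighted_failed = [c for c in comps if c.weight > 0 and c.value is None]
    overall: float | None
    if weighted_failed:
        logger.warning(
            "overall smoothness not computed: %d weighted component(s) degenerate",
            len(weighted_failed),
        )
        overall = None
    else:
        lam = [c.value for c in comps]
        overall = overall_smoothness(
            [v if v is not None else 0.0 for v in lam], list(weights)
        )
    return SmoothnessResult(measure, tuple(comps), overall, task_label, params)


def detect_dwell_boundaries(
    v: SpeedProfile,
    speed_fraction: float = 0.05,
    min_dwell: float = 0.1,
) -> list[float]:
    """Heuristic dwell detector: midpoints of sustained low-speed periods.

    Convenience only — event-based segmentation is meant to be driven by
    task knowledge, and this helper is not a substitute for it. A dwell is
    a run of samples with speed below ``speed_fraction * v_peak`` lasting at
    least ``min_dwell`` seconds; the run's midpoint is proposed as a
    component boundary.
    """
    v.require_movement()
    low = v.values < speed_fraction * v.v_peak
    boundaries: list[float] = []
    run_start = None
    for i, flag in enumerate(np.append(low, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if (i - run_start) * v.dt >= min_dwell and run_start > 0 and i < v.values.size:
                boundaries.append(v.t1 + v.dt * (run_start + i - 1) / 2.0)
            run_start = None
    return boundaries
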