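"""Signal containers and preprocessing transforms.

Smoothness measures consume a nonnegative scalar profile (typically speed).
Measured variables arrive in different spaces — position traces, raw
accelerometer output, force/torque — and each needs its own transform before
a measure applies:

* position  -> speed ``||dx/dt||`` (for spectral measures and, after one more
  derivative, jerk-based measures),
* 3-axis accelerometer -> gravity-subtracted acceleration magnitude
  ``| ||a|| - g |`` (spectral measures) or jerk magnitude ``||da/dt||``
  (jerk-based measures),
* force/torque -> magnitude of the first (spectral) or third (jerk-based)
  time derivative.

The accelerometer rule assumes a quasi-static gravity direction and the
force/torque rules are heuristic extrapolations; both are provided as stated
in the movement-analysis literature but flagged experimental in the docs.

Differentiation uses second-order central differences in the interior and
one-sided differences at the edges (``numpy.gradient``), so a derivative
keeps the sample count of its source and stays aligned with any event-based
segmentation of the original recording. Interior accuracy is O(dt^2); the
two edge samples are O(dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    DegenerateInputError,
    InputTooShortError,
    ParameterError,
    ShapeError,
)

STANDARD_GRAVITY = 9.81  # m/s^2

__all__ = [
    "SampledSignal",
    "SpeedProfile",
    "speed_from_position",
    "accel_magnitude_profile",
    "derivative_magnitude",
    "lowpass_filter",
    "STANDARD_GRAVITY",
]


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled, possibly multi-channel time series.

    Parameters
    ----------
    start_time : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds. Sampling is uniform by construction; no
        per-sample timestamps are stored.
    channels : tuple of str
        Ordered channel names.
    values : ndarray, shape (n_samples, n_channels)
        Sample matrix.
    """

    start_time: float
    dt: float
    channels: tuple[str, ...]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.ndim != 2:
            raise ShapeError(f"values must be 2-D (samples x channels), got ndim={vals.ndim}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if vals.shape[0] < 4:
            raise InputTooShortError(f"need at least 4 samples, got {vals.shape[0]}")
        if len(self.channels) != vals.shape[1]:
            raise ShapeError(
                f"{len(self.channels)} channel names for {vals.shape[1]} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(self.n_samples)


@dataclass(frozen=True)
class SpeedProfile:
    """Nonnegative scalar profile v(t) on [t1, t2] — the measures' input.

    Despite the name the values need not be a kinematic speed: the
    accelerometer and force/torque transforms produce profiles in other
    spaces, recorded in ``space``.
    """

    t1: float
    dt: float
    values: np.ndarray
    space: str = "speed"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", vals)
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if vals.size < 3:
            raise InputTooShortError(f"need at least 3 samples, got {vals.size}")
        if np.any(vals < -1e-12 * max(1.0, np.max(np.abs(vals), initial=0.0))):
            raise ShapeError("speed profile values must be nonnegative")
        object.__setattr__(self, "values", np.maximum(vals, 0.0))

    @property
    def t2(self) -> float:
        return self.t1 + (self.values.size - 1) * self.dt

    @property
    def duration(self) -> float:
        return self.t2 - self.t1

    @property
    def v_peak(self) -> float:
        return float(np.max(self.values))

    @property
    def peak_time(self) -> float:
        # first occurrence on ties
        return self.t1 + self.dt * int(np.argmax(self.values))

    @property
    def times(self) -> np.ndarray:
        return self.t1 + self.dt * np.arange(self.values.size)

    def require_movement(self) -> None:
        """Reject an all-zero profile: a fixed posture has no smoothness."""
        if self.v_peak <= 0.0:
            raise DegenerateInputError(
                "profile is identically zero; smoothness of a fixed posture is undefined"
            )


def _snap_derivative_noise(
    mag: np.ndarray, source: np.ndarray, dt: float, order: int
) -> np.ndarray:
    """Zero out derivative magnitudes below the float round-off floor.

    Differentiating a constant-valued stretch (a dwell) leaves residuals of
    order eps * |x| / dt^order; without snapping them to zero a pure
    posture would masquerade as a (vanishingly small) movement and the
    degenerate-input guard on the measures would never trigger.
    """
    floor = 1e-12 * float(np.max(np.abs(source), initial=0.0)) / dt**order
    out = mag.copy()
    out[out < floor] = 0.0
    return out


def _nth_gradient(values: np.ndarray, dt: float, order: int) -> np.ndarray:
    out = values
    for _ in range(order):
        out = np.gradient(out, dt, axis=0, edge_order=2)
    return out


def lowpass_filter(sig: SampledSignal, cutoff_hz: float, order: int = 4) -> SampledSignal:
    """Zero-phase Butterworth low-pass, applied to every channel.

    Off by default everywhere in the library. When comparing recordings,
    apply the *same* filter to all of them — the same movement filtered
    differently yields different smoothness estimates.
    """
    fs = 1.0 / sig.dt
    if not 0 < cutoff_hz < fs / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={fs / 2} Hz)")
    b, a = butter(order, cutoff_hz, fs=fs)
    filtered = filtfilt(b, a, sig.values, axis=0)
    return SampledSignal(sig.start_time, sig.dt, sig.channels, filtered, sig.units)


def speed_from_position(
    pos: SampledSignal, smoothing_cutoff_hz: float | None = None
) -> SpeedProfile:
    """Speed profile ``||dx/dt||_2`` of a D-dimensional position trace.

    Parameters
    ----------
    pos : SampledSignal
        Position in task or joint space; one column per spatial dimension.
    smoothing_cutoff_hz : float, optional
        If given, low-pass the position before differentiating.
    """
    if pos.n_samples < 4:
        raise InputTooShortError("need at least 4 position samples")
    if smoothing_cutoff_hz is not None:
        pos = lowpass_filter(pos, smoothing_cutoff_hz)
    vel = _nth_gradient(pos.values, pos.dt, 1)
    speed = np.linalg.norm(vel, axis=1)
    speed = _snap_derivative_noise(speed, pos.values, pos.dt, 1)
    return SpeedProfile(pos.start_time, pos.dt, speed, space="speed")


def accel_magnitude_profile(
    acc: SampledSignal, g: float = STANDARD_GRAVITY
) -> SpeedProfile:
    """Gravity-subtracted acceleration magnitude ``| ||a(t)|| - g |``.

    Removes the dominant static-gravity DC component from 3-axis
    accelerometer data so that spectral smoothness measures are not swamped
    by it. The result lives in acceleration space, not velocity space
    (``space="acceleration"`` on the returned profile). Assumes the sensor
    orientation changes slowly relative to the movement; experimental.
    """
    if len(acc.channels) != 3:
        raise ShapeError(f"accelerometer signal must have 3 channels, got {len(acc.channels)}")
    if g <= 0:
        raise ParameterError(f"gravity must be positive, got {g}")
    mag = np.abs(np.linalg.norm(acc.values, axis=1) - g)
    return SpeedProfile(acc.start_time, acc.dt, mag, space="acceleration")


def derivative_magnitude(x: SampledSignal, order: int) -> SpeedProfile:
    """Per-sample Euclidean norm of the order-th time derivative.

    Used for force/torque channels (order 1 for spectral measures, order 3
    for jerk-based measures) and for jerk from accelerometer data (order 1).
    """
    if order not in (1, 2, 3):
        raise ParameterError(f"derivative order must be 1, 2 or 3, got {order}")
    if x.n_samples < order + 3:
        raise InputTooShortError(
            f"need at least {order + 3} samples for order-{order} derivative, got {x.n_samples}"
        )
    deriv = _nth_gradient(x.values, x.dt, order)
    mag = np.linalg.norm(deriv, axis=1)
    mag = _snap_derivative_noise(mag, x.values, x.dt, order)
    return SpeedProfile(x.start_time, x.dt, mag, space=f"derivative-{order}")
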