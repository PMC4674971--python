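"""Synthetic movement generator.

Point-to-point reaches are modelled as minimum-jerk strokes: the speed
profile of a healthy reach of amplitude D and duration T is the bell curve

    v(tau * T) = (D / T) * 30 * tau^2 * (1 - tau)^2,   tau in [0, 1],

which starts and ends at zero speed, peaks at 1.875 * D / T at mid-movement
and integrates to D. Impaired, intermittent reaches ("stroke-like") are
modelled as superpositions of several such submovements with temporal gaps.
Rhythmic movements alternate minimum-jerk strokes between two targets P and
Q, each stroke followed by a dwell at the target; the generator returns the
position trace together with the ground-truth per-half-cycle segmentation.

Measurement noise is additive Gaussian white noise whose variance is set
from the signal power and a requested signal-to-noise ratio. Dwell is
modelled as exactly constant position (an idealised movement arrest);
real sensors would superimpose noise there too, which ``add_noise``
reintroduces when applied to the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import Segmentation
from .errors import DegenerateInputError, ParameterError
from .profiles import SampledSignal, SpeedProfile

__all__ = [
    "SubmovementSpec",
    "RhythmicSpec",
    "NoiseSpec",
    "min_jerk_speed",
    "min_jerk_position",
    "superpose_submovements",
    "rhythmic_movement",
    "add_noise",
    "healthy_reach",
    "stroke_reach",
    "PRESETS",
    "preset_rhythmic",
]


@dataclass(frozen=True)
class SubmovementSpec:
    """One minimum-jerk submovement: onset time, amplitude D, duration T."""

    onset: float
    amplitude: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.amplitude <= 0:
            raise ParameterError(f"amplitude must be positive, got {self.amplitude}")


@dataclass(frozen=True)
class RhythmicSpec:
    """Back-and-forth movement between targets P and Q.

    n_cycles full cycles; each half-cycle is a stroke of duration
    ``movement_time`` (MT) followed by a dwell of ``dwell_time`` (DT) at the
    target, so one component lasts MT + DT and the trace has
    2 * n_cycles components.
    """

    n_cycles: int
    movement_time: float
    dwell_time: float
    amplitude: float = 0.1
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.movement_time <= 0:
            raise ParameterError("movement_time must be positive")
        if self.dwell_time < 0:
            raise ParameterError("dwell_time must be nonnegative")

    @property
    def q(self) -> float:
        return self.p + self.amplitude

    @property
    def component_time(self) -> float:
        return self.movement_time + self.dwell_time

    @property
    def n_components(self) -> int:
        return 2 * self.n_cycles


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-noise description: SNR = signal power / noise power."""

    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ParameterError(f"snr must be positive, got {self.snr}")


def _check_resolution(duration: float, dt: float) -> None:
    if dt > duration / 50.0:
        raise ParameterError(
            f"dt={dt} too coarse for a {duration} s movement; need dt <= T/50"
        )


def min_jerk_speed(D: float, T: float, dt: float, t0: float = 0.0) -> SpeedProfile:
    """Minimum-jerk speed profile of a reach of amplitude D and duration T."""
    _check_resolution(T, dt)
    n = int(round(T / dt)) + 1
    tau = np.arange(n) * dt / T
    tau = np.clip(tau, 0.0, 1.0)
    v = (D / T) * 30.0 * tau**2 * (1.0 - tau) ** 2
    return SpeedProfile(t0, dt, v)


def min_jerk_position(D: float, T: float, dt: float) -> np.ndarray:
    """Minimum-jerk position x(tau*T) = D * (10 tau^3 - 15 tau^4 + 6 tau^5)."""
    _check_resolution(T, dt)
    n = int(round(T / dt)) + 1
    tau = np.clip(np.arange(n) * dt / T, 0.0, 1.0)
    return D * (10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5)


def superpose_submovements(specs: list[SubmovementSpec], dt: float) -> SpeedProfile:
    """Pointwise sum of minimum-jerk speed profiles placed at their onsets.

    The span runs from the first onset to the last offset. Submovements may
    overlap; heavily overlapping submovements merge into a single-peaked
    profile, while finite gaps produce one speed peak per submovement.
    """
    if not specs:
        raise ParameterError("need at least one submovement")
    specs = sorted(specs, key=lambda s: s.onset)
    t_start = specs[0].onset
    t_end = max(s.onset + s.duration for s in specs)
    n = int(round((t_end - t_start) / dt)) + 1
    t = t_start + np.arange(n) * dt
    v = np.zeros(n)
    for s in specs:
        _check_resolution(s.duration, dt)
        tau = (t - s.onset) / s.duration
        inside = (tau >= 0.0) & (tau <= 1.0)
        v[inside] += (s.amplitude / s.duration) * 30.0 * tau[inside] ** 2 * (1.0 - tau[inside]) ** 2
    return SpeedProfile(t_start, dt, v)


def rhythmic_movement(
    spec: RhythmicSpec, dt: float
) -> tuple[SampledSignal, Segmentation]:
    """Alternating minimum-jerk strokes P->Q, Q->P, each followed by a dwell.

    Returns the 1-D position trace and the ground-truth segmentation with
    boundaries t_i = (i - 1) * (MT + DT), one component per half-cycle
    (stroke plus its trailing dwell), labelled "P->Q" / "Q->P".
    """
    mt, dwt = spec.movement_time, spec.dwell_time
    stroke = min_jerk_position(spec.amplitude, mt, dt)
    n_stroke = stroke.size - 1  # samples per stroke excluding its endpoint
    n_dwell = int(round(dwt / dt))
    n_comp = n_stroke + n_dwell
    total = spec.n_components * n_comp + 1
    pos = np.empty(total)
    labels = []
    at_q = False
    for i in range(spec.n_components):
        seg_vals = spec.p + (spec.amplitude - stroke if at_q else stroke)
        lo = i * n_comp
        pos[lo : lo + n_stroke] = seg_vals[:-1]
        pos[lo + n_stroke : lo + n_comp] = seg_vals[-1]
        labels.append("Q->P" if at_q else "P->Q")
        at_q = not at_q
    pos[-1] = spec.p  # even number of half-cycles ends back at P
    sig = SampledSignal(0.0, dt, ("x",), pos[:, None], units="m")
    boundaries = tuple(i * spec.component_time for i in range(spec.n_components + 1))
    return sig, Segmentation(boundaries, tuple(labels))


def add_noise(v: SpeedProfile | SampledSignal, noise: NoiseSpec):
    """Add Gaussian white noise at the requested SNR.

    Noise variance is mean(signal^2) / snr, computed over all samples (and
    channels). Reproducible: equal seeds give identical noise. A
    SpeedProfile input is clipped at zero, since measures require
    nonnegative profiles — this mimics how a measured speed magnitude
    cannot be negative.
    """
    values = v.values
    power = float(np.mean(values**2))
    if power <= 0.0:
        raise DegenerateInputError("zero-power signal; SNR undefined")
    sigma = np.sqrt(power / noise.snr)
    rng = np.random.default_rng(noise.seed)
    noisy = values + rng.normal(0.0, sigma, size=values.shape)
    if isinstance(v, SpeedProfile):
        return SpeedProfile(v.t1, v.dt, np.maximum(noisy, 0.0), v.space)
    return SampledSignal(v.start_time, v.dt, v.channels, noisy, v.units)


def healthy_reach(D: float = 0.1, T: float = 1.0, dt: float = 0.01) -> SpeedProfile:
    """Single minimum-jerk reach: the canonical smooth movement."""
    return min_jerk_speed(D, T, dt)


def stroke_reach(
    D: float = 0.1, T: float = 1.0, dt: float = 0.01, gap: float = 0.5, n_sub: int = 3
) -> SpeedProfile:
    """Intermittent reach: n_sub equal submovements with finite gaps.

    Each submovement covers D/n_sub in time T; successive onsets are spaced
    T + gap apart, so the speed drops to zero between submovements and the
    profile has n_sub distinct peaks.
    """
    specs = [
        SubmovementSpec(onset=i * (T + gap), amplitude=D / n_sub, duration=T)
        for i in range(n_sub)
    ]
    return superpose_submovements(specs, dt)


# Rhythmic presets from the back-and-forth example: Ma (10 cycles,
# component time 1.25 s), Mc (10 cycles, component time 0.7 s, the same
# stroke shape traversed faster) and Md (Ma's timing, 20 cycles). The
# split of component time into MT and DT keeps MT:DT = 4:1 in all three.
# Mb replaces each smooth stroke with a 3-submovement superposition at
# equal MT — a less smooth mover with Ma's timing.
PRESETS: dict[str, RhythmicSpec] = {
    "Ma": RhythmicSpec(n_cycles=10, movement_time=1.0, dwell_time=0.25),
    "Mc": RhythmicSpec(n_cycles=10, movement_time=0.56, dwell_time=0.14),
    "Md": RhythmicSpec(n_cycles=20, movement_time=1.0, dwell_time=0.25),
}


def _intermittent_stroke_position(D: float, T: float, dt: float, n_sub: int = 3) -> np.ndarray:
    """Position of a stroke made of n_sub back-to-back submovements within T."""
    sub_T = T / n_sub
    n = int(round(T / dt)) + 1
    pos = np.zeros(n)
    for i in range(n_sub):
        lo = int(round(i * sub_T / dt))
        n_piece = int(round(sub_T / dt)) + 1
        tau = np.clip(np.arange(n_piece) * dt / sub_T, 0.0, 1.0)
        piece = (D / n_sub) * (10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5)
        pos[lo : lo + n_piece] = i * D / n_sub + piece
    pos[lo + n_piece :] = D
    return pos


def preset_rhythmic(name: str, dt: float = 0.01) -> tuple[SampledSignal, Segmentation]:
    """Build a named rhythmic fixture: 'Ma', 'Mb', 'Mc' or 'Md'."""
    if name == "Mb":
        spec = PRESETS["Ma"]
        sig, seg = rhythmic_movement(spec, dt)
        stroke = _intermittent_stroke_position(spec.amplitude, spec.movement_time, dt)
        n_stroke = stroke.size - 1
        n_comp = n_stroke + int(round(spec.dwell_time / dt))
        pos = sig.values[:, 0].copy()
        at_q = False
        for i in range(spec.n_components):
            vals = spec.p + (spec.amplitude - stroke if at_q else stroke)
            pos[i * n_comp : i * n_comp + n_stroke] = vals[:-1]
            at_q = not at_q
        return SampledSignal(0.0, dt, ("x",), pos[:, None], units="m"), seg
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ParameterError(f"unknown preset {name!r}; choose Ma, Mb, Mc or Md") from None
    return rhythmic_movement(spec, dt)
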