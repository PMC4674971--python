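"""Validity and reliability studies for the smoothness measures.

Three runnable studies, each returning a :class:`SweepResult` that can be
dumped to CSV/JSON:

* ``validity_sweep`` — noise-free measure values on submovement
  superpositions, varying the number of submovements at fixed gap and the
  inter-submovement gap at fixed count; a valid measure must decrease
  strictly along both factors.
* ``reliability_sweep`` — Monte-Carlo mean and standard deviation of a
  measure under additive white noise across a grid of SNRs, against the
  noise-free reference value.
* ``speed_bias_study`` — the same movement shape rescaled in amplitude and
  duration under *constant-power* noise: slower movements carry less signal
  power, hence lower effective SNR, so noise-fragile measures systematically
  underestimate the smoothness of slow movements.

Because SPARC and LDLJ live on different scales, cross-measure comparisons
normalise each measure's deviation by its own healthy-vs-intermittent
fixture gap (the score difference between a single-submovement reach and a
3-submovement reach).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .measures import MeasureParams, compute_measure
from .simulate import (
    NoiseSpec,
    SubmovementSpec,
    add_noise,
    healthy_reach,
    stroke_reach,
    superpose_submovements,
)

__all__ = [
    "SweepResult",
    "validity_sweep",
    "reliability_sweep",
    "speed_bias_study",
    "fixture_gap",
]

MONOTONE_TOL = 1e-9  # strictness tolerance for noise-free monotonicity flags


@dataclass
class SweepResult:
    """Grid of measure values plus metadata for reproducibility."""

    study: str
    table: pd.DataFrame
    n_reps: int = 1
    seed: int | None = None
    flags: dict = field(default_factory=dict)

    def to_json_summary(self) -> dict:
        return {
            "study": self.study,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "flags": self.flags,
            "table": self.table.to_dict(orient="records"),
        }


def _submovement_profile(n_sub: int, gap: float, dt: float, D: float = 0.1, T: float = 1.0):
    specs = [
        SubmovementSpec(onset=i * (T + gap), amplitude=D / max(n_sub, 1), duration=T)
        for i in range(n_sub)
    ]
    return superpose_submovements(specs, dt)


def validity_sweep(
    measure: str,
    n_range: Sequence[int] = (1, 2, 3, 4),
    gap_range: Sequence[float] = (0.2, 0.4, 0.8),
    dt: float = 0.01,
    params: MeasureParams = MeasureParams(),
    fixed_gap: float = 0.5,
    fixed_n: int = 2,
) -> SweepResult:
    """Noise-free measure response to submovement count and gap.

    Flags ``monotone_in_n`` / ``monotone_in_gap`` report whether the measure
    strictly decreases along each factor (more submovements, or larger
    gaps, meaning a less smooth movement must score lower).
    """
    if any(n < 1 or n > 6 for n in n_range):
        raise ValueError("submovement counts must be within 1..6")
    rows = []
    for n in n_range:
        v = _submovement_profile(n, fixed_gap, dt)
        rows.append({"factor": "n_submovements", "level": n, "value": compute_measure(measure, v, params)})
    for gap in gap_range:
        v = _submovement_profile(fixed_n, gap, dt)
        rows.append({"factor": "gap", "level": gap, "value": compute_measure(measure, v, params)})
    table = pd.DataFrame(rows)
    by_n = table[table.factor == "n_submovements"].value.to_numpy()
    by_gap = table[table.factor == "gap"].value.to_numpy()
    flags = {
        "monotone_in_n": bool(np.all(np.diff(by_n) < -MONOTONE_TOL)),
        "monotone_in_gap": bool(np.all(np.diff(by_gap) < -MONOTONE_TOL)),
    }
    return SweepResult(study=f"validity[{measure}]", table=table, flags=flags)


def reliability_sweep(
    measure: str,
    snr_list: Sequence[float] = (1000.0, 100.0, 10.0, 1.0),
    n_reps: int = 50,
    seed: int = 0,
    dt: float = 0.01,
    params: MeasureParams = MeasureParams(),
) -> SweepResult:
    """Monte-Carlo spread of a measure under additive noise on a reach.

    Noise replicates are seeded deterministically from ``seed``; each table
    row records the per-SNR mean, std and mean shift from the noise-free
    reference.
    """
    if n_reps < 20:
        raise ValueError("need at least 20 replicates for stable statistics")
    clean = healthy_reach(dt=dt)
    reference = compute_measure(measure, clean, params)
    rows = [{"snr": np.inf, "mean": reference, "std": 0.0, "mean_shift": 0.0}]
    ss = np.random.SeedSequence(seed)
    for snr in snr_list:
        child_seeds = ss.spawn(1)[0].generate_state(n_reps) % (2**31)
        vals = np.array(
            [
                compute_measure(measure, add_noise(clean, NoiseSpec(snr, int(s))), params)
                for s in child_seeds
            ]
        )
        rows.append(
            {
                "snr": snr,
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=1)),
                "mean_shift": float(vals.mean() - reference),
            }
        )
    table = pd.DataFrame(rows)
    return SweepResult(
        study=f"reliability[{measure}]", table=table, n_reps=n_reps, seed=seed
    )


def fixture_gap(measure: str, dt: float = 0.01, params: MeasureParams = MeasureParams()) -> float:
    """Score gap between the smooth and intermittent reference reaches.

    Used to express deviations of different measures on a comparable scale.
    """
    smooth = compute_measure(measure, healthy_reach(dt=dt), params)
    rough = compute_measure(measure, stroke_reach(dt=dt), params)
    return abs(smooth - rough)


def speed_bias_study(
    measure: str,
    duration_scales: Sequence[float] = (1.0, 2.0, 4.0),
    noise_power: float = 1e-5,
    n_reps: int = 50,
    seed: int = 0,
    dt: float = 0.01,
    params: MeasureParams = MeasureParams(),
) -> SweepResult:
    """Bias of a measure on slowed copies of the same movement shape.

    Each scale alpha stretches the reference reach to duration alpha * T at
    the same amplitude, dividing its speed by alpha; under constant noise
    power the effective SNR falls as the movement slows. Reports, per scale,
    the empirical SNR and the mean bias relative to that scale's noise-free
    value.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for alpha in duration_scales:
        if alpha <= 0:
            raise ValueError("duration scales must be positive")
        clean = healthy_reach(T=alpha, dt=dt)
        reference = compute_measure(measure, clean, params)
        sig_power = float(np.mean(clean.values**2))
        snr = sig_power / noise_power
        child_seeds = ss.spawn(1)[0].generate_state(n_reps) % (2**31)
        vals = np.array(
            [
                compute_measure(measure, add_noise(clean, NoiseSpec(snr, int(s))), params)
                for s in child_seeds
            ]
        )
        rows.append(
            {
                "duration_scale": alpha,
                "empirical_snr": snr,
                "reference": reference,
                "mean": float(vals.mean()),
                "bias": float(vals.mean() - reference),
                "std": float(vals.std(ddof=1)),
            }
        )
    table = pd.DataFrame(rows)
    return SweepResult(
        study=f"speed_bias[{measure}]", table=table, n_reps=n_reps, seed=seed
    )
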