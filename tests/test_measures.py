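"""Smoothness measures against closed-form and brute-force oracles.

Key frozen values (independent derivations):

* minimum-jerk DLJ, duration exponent 3: the second derivative of
  v(tau) = 30 (D/T) tau^2 (1-tau)^2 is (D/T^3)(60 - 360 tau + 360 tau^2),
  whose squared integral over one duration is 720 D^2 / T^5, and
  v_peak = 1.875 D / T, so DLJ = -720 / 1.875^2 = -204.8 for any D, T.
* minimum-jerk LDLJ = -ln(204.8) = -5.32196...
"""

import numpy as np
import pytest
from scipy.integrate import simpson

from kinesmooth import (
    MeasureParams,
    SpeedProfile,
    Spectrum,
    adaptive_cutoff,
    dimensionless_jerk,
    healthy_reach,
    log_dimensionless_jerk,
    magnitude_spectrum,
    number_of_peaks,
    sal,
    sparc,
    stroke_reach,
    superpose_submovements,
    SubmovementSpec,
)
from kinesmooth.errors import DegenerateInputError, ParameterError

from conftest import DT

MINJERK_DLJ = -204.8
MINJERK_LDLJ = -np.log(204.8)


def dlj_oracle(specs: list[SubmovementSpec], n_dense: int = 20001) -> float:
    """Quadrature oracle for DLJ (e=3) of superposed minimum-jerk strokes.

    Uses the analytic second derivative of each submovement's speed on a
    dense grid — independent of the finite-difference implementation.
    """
    t0 = min(s.onset for s in specs)
    t1 = max(s.onset + s.duration for s in specs)
    t = np.linspace(t0, t1, n_dense)
    v = np.zeros_like(t)
    vpp = np.zeros_like(t)
    for s in specs:
        tau = (t - s.onset) / s.duration
        inside = (tau >= 0) & (tau <= 1)
        ti = tau[inside]
        v[inside] += (s.amplitude / s.duration) * 30 * ti**2 * (1 - ti) ** 2
        vpp[inside] += (s.amplitude / s.duration**3) * (60 - 360 * ti + 360 * ti**2)
    return -((t1 - t0) ** 3) * simpson(vpp**2, x=t) / np.max(v) ** 2


def cutoff_oracle(freq: np.ndarray, vhat: np.ndarray, threshold: float, wmax: float) -> float:
    """Brute-force scan: smallest grid omega with the whole tail below threshold."""
    candidates = [
        w for i, w in enumerate(freq) if np.all(vhat[i + 1 :] < threshold)
    ]
    w = min(candidates)
    return min(max(w, freq[1]), wmax)


class TestDimensionlessJerk:
    def test_minjerk_closed_form(self, minjerk_speed, params):
        assert dimensionless_jerk(minjerk_speed, params) == pytest.approx(
            MINJERK_DLJ, rel=2e-2
        )

    def test_amplitude_invariance_exact(self, minjerk_speed, params):
        scaled = SpeedProfile(0.0, DT, 7.3 * minjerk_speed.values)
        assert dimensionless_jerk(scaled, params) == pytest.approx(
            dimensionless_jerk(minjerk_speed, params), rel=1e-12
        )

    def test_movement_scale_invariance_with_exponent_3(self, params):
        # same shape traversed in double the time: DLJ (e=3) unchanged
        slow = healthy_reach(D=0.1, T=2.0, dt=DT)
        fast = healthy_reach(D=0.1, T=1.0, dt=DT)
        assert dimensionless_jerk(slow, params) == pytest.approx(
            dimensionless_jerk(fast, params), rel=1e-2
        )

    def test_printed_exponent_5_scales_with_duration_squared(self):
        p5 = MeasureParams(dlj_duration_exponent=5)
        slow = healthy_reach(D=0.1, T=2.0, dt=DT)
        fast = healthy_reach(D=0.1, T=1.0, dt=DT)
        ratio = dimensionless_jerk(slow, p5) / dimensionless_jerk(fast, p5)
        assert ratio == pytest.approx(4.0, rel=1e-2)

    def test_gapped_submovements_more_negative_than_one(self, params):
        one = [SubmovementSpec(0.0, 0.1, 1.0)]
        two = [SubmovementSpec(0.0, 0.05, 1.0), SubmovementSpec(1.5, 0.05, 1.0)]
        v_two = superpose_submovements(two, DT)
        got = dimensionless_jerk(v_two, params)
        assert got < dlj_oracle(one)
        assert got == pytest.approx(dlj_oracle(two), rel=5e-2)

    def test_all_zero_profile_rejected(self, params):
        with pytest.raises(DegenerateInputError):
            dimensionless_jerk(SpeedProfile(0.0, DT, np.zeros(100)), params)


class TestLogDimensionlessJerk:
    def test_is_negative_log_of_dlj_magnitude(self, stroke_speed, params):
        assert log_dimensionless_jerk(stroke_speed, params) == pytest.approx(
            -np.log(abs(dimensionless_jerk(stroke_speed, params))), abs=1e-12
        )

    def test_minjerk_value(self, minjerk_speed, params):
        assert log_dimensionless_jerk(minjerk_speed, params) == pytest.approx(
            MINJERK_LDLJ, abs=0.05
        )

    def test_ordering_minjerk_above_stroke(self, minjerk_speed, stroke_speed, params):
        assert log_dimensionless_jerk(minjerk_speed, params) > log_dimensionless_jerk(
            stroke_speed, params
        )


class TestNumberOfPeaks:
    def test_minjerk_single_peak(self, minjerk_speed, params):
        assert number_of_peaks(minjerk_speed, params) == -1

    def test_three_separated_submovements(self, stroke_speed, params):
        assert number_of_peaks(stroke_speed, params) == -3

    def test_monotone_ramp_has_no_interior_maximum(self, params):
        ramp = SpeedProfile(0.0, DT, np.linspace(0, 1, 50))
        assert number_of_peaks(ramp, params) == 0

    def test_prominence_filters_small_ripples(self, minjerk_speed):
        # carve a tiny asymmetric notch at the peak: the secondary maximum
        # has ~1e-3 prominence and must vanish under a prominence threshold
        notched = minjerk_speed.values.copy()
        notched[50] *= 0.995
        notched[49] *= 0.999
        v = SpeedProfile(0.0, DT, notched)
        assert number_of_peaks(v, MeasureParams()) == -2
        assert number_of_peaks(v, MeasureParams(np_min_prominence=0.01)) == -1


class TestMagnitudeSpectrum:
    def test_constant_profile_concentrates_at_dc(self, params):
        spec = magnitude_spectrum(SpeedProfile(0.0, DT, np.full(128, 2.0)), params)
        assert spec.normalized[0] == 1.0
        # rectangular-window leakage: away from the main lobe everything is tiny
        assert np.all(spec.normalized[40:] < 0.05)

    def test_parseval(self, minjerk_speed, params):
        spec = magnitude_spectrum(minjerk_speed, params)
        n_fft = 2 * (spec.magnitude.size - 1)
        # rfft halves the spectrum: double all bins except DC and Nyquist
        weights = np.full(spec.magnitude.size, 2.0)
        weights[0] = weights[-1] = 1.0
        lhs = np.sum(weights * spec.magnitude**2)
        rhs = n_fft * np.sum(minjerk_speed.values**2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_zero_padding_refines_but_preserves_shared_bins(self, minjerk_speed):
        s1 = magnitude_spectrum(minjerk_speed, MeasureParams(zero_padding_factor=4))
        s2 = magnitude_spectrum(minjerk_speed, MeasureParams(zero_padding_factor=8))
        assert np.allclose(s2.magnitude[::2], s1.magnitude, atol=1e-9)


class TestAdaptiveCutoff:
    def _spectrum(self, vhat, dw=1.0):
        vhat = np.asarray(vhat, dtype=float)
        freq = dw * np.arange(vhat.size)
        return Spectrum(freq=freq, magnitude=vhat, normalized=vhat)

    def test_upper_bound_binds_when_spectrum_stays_high(self):
        spec = self._spectrum(np.ones(200), dw=1.0)
        p = MeasureParams(max_cutoff=40 * np.pi)
        assert adaptive_cutoff(spec, p) == pytest.approx(40 * np.pi)

    def test_four_bin_toy_spectrum(self):
        spec = self._spectrum([1.0, 0.5, 0.04, 0.01])
        assert adaptive_cutoff(spec, MeasureParams(threshold=0.05)) == 1.0

    def test_resurgent_bump_pushes_cutoff_past_it(self):
        vhat = [1.0, 0.5, 0.01, 0.01, 0.2, 0.01, 0.01]
        spec = self._spectrum(vhat)
        p = MeasureParams(threshold=0.05)
        got = adaptive_cutoff(spec, p)
        assert got == cutoff_oracle(spec.freq, spec.normalized, 0.05, p.max_cutoff)
        assert got == 4.0

    def test_matches_brute_force_on_random_spectra(self):
        rng = np.random.default_rng(7)
        p = MeasureParams(threshold=0.05, max_cutoff=60.0)
        for _ in range(50):
            vhat = np.concatenate([[1.0], rng.uniform(0, 0.5, 99)])
            spec = self._spectrum(vhat, dw=rng.uniform(0.1, 1.0))
            assert adaptive_cutoff(spec, p) == pytest.approx(
                cutoff_oracle(spec.freq, spec.normalized, 0.05, 60.0)
            )


class TestSparc:
    @pytest.mark.parametrize("alpha", [0.5, 0.75, 1.5, 2.0])
    def test_temporal_scaling_invariance(self, minjerk_speed, params, alpha):
        scaled = healthy_reach(D=0.1, T=alpha, dt=DT)
        assert sparc(scaled, params) == pytest.approx(
            sparc(minjerk_speed, params), abs=1e-2
        )

    def test_minjerk_above_normative_bound(self, minjerk_speed, params):
        assert sparc(minjerk_speed, params) >= -1.6

    def test_ordering_in_submovement_count(self, params):
        vals = []
        for n in (1, 2, 3):
            specs = [SubmovementSpec(i * 1.5, 0.1 / n, 1.0) for i in range(n)]
            vals.append(sparc(superpose_submovements(specs, DT), params))
        assert vals[0] > vals[1] > vals[2]

    def test_amplitude_invariance(self, minjerk_speed, params):
        scaled = SpeedProfile(0.0, DT, 123.0 * minjerk_speed.values)
        assert sparc(scaled, params) == pytest.approx(sparc(minjerk_speed, params), abs=1e-9)


class TestSal:
    def _broadband_pulse(self):
        # 10 ms Gaussian pulse at 1 kHz: spectrum stays above threshold past
        # 20 Hz, so the adaptive cutoff saturates at its upper bound
        dt = 1e-3
        t = dt * np.arange(201)
        return SpeedProfile(0.0, dt, np.exp(-((t - 0.1) ** 2) / (2 * 0.01**2)))

    def test_equals_sparc_when_cutoff_saturates(self, params):
        v = self._broadband_pulse()
        spec = magnitude_spectrum(v, params)
        assert adaptive_cutoff(spec, params) == pytest.approx(params.max_cutoff)
        assert sal(v, params) == pytest.approx(sparc(v, params), abs=1e-12)

    def test_violates_temporal_scaling(self, minjerk_speed, params):
        slow = healthy_reach(D=0.1, T=2.0, dt=DT)
        assert abs(sal(slow, params) - sal(minjerk_speed, params)) > 1e-2

    def test_zero_profile_rejected(self, params):
        with pytest.raises(DegenerateInputError):
            sal(SpeedProfile(0.0, DT, np.zeros(100)), params)

    def test_amplitude_invariance(self, minjerk_speed, params):
        scaled = SpeedProfile(0.0, DT, 0.01 * minjerk_speed.values)
        assert sal(scaled, params) == pytest.approx(sal(minjerk_speed, params), abs=1e-9)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold": 0.0},
            {"threshold": 1.0},
            {"max_cutoff": -1.0},
            {"zero_padding_factor": 0},
            {"dlj_duration_exponent": 4},
            {"np_min_prominence": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MeasureParams(**kwargs)
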