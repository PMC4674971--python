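# Methods

## What the package measures

Movement smoothness is the quality of continuality of a movement: a healthy
point-to-point reach has a single bell-shaped speed profile, while impaired
movement shows intermittency — extra speed peaks, decelerate/accelerate
alternations, or outright movement arrests. A valid smoothness measure must
be dimensionless (independent of movement amplitude and duration) and must
decrease monotonically as intermittency grows, e.g. as the number of
submovements in a movement, or the interval between them, increases.

All measures here return values ≤ 0 with *closer to zero = smoother*.

### Spectral arc length (SPARC) and its fixed-cutoff ancestor (SAL)

For a speed profile v(t) with Fourier magnitude spectrum V(ω), normalised by
the DC magnitude, V̂(ω) = V(ω)/V(0), the spectral arc length is

    −∫₀^ωc √[ (1/ωc)² + (dV̂/dω)² ] dω.

SAL fixes ωc = 40π rad/s (20 Hz). SPARC instead selects ωc adaptively: the
smallest frequency beyond which V̂ stays below a threshold V̄ (default 0.05),
capped at ωc_max (default 40π). Intermittency spreads spectral content to
higher frequencies and ripples the spectrum, lengthening the arc. The
adaptive cutoff is what makes SPARC invariant to temporal scaling of the
movement; SAL is not, which is the reason SPARC superseded it.

### Jerk-based measures (DLJ, LDLJ)

    DLJ = −( (t₂−t₁)^e / v_peak² ) ∫ |d²v/dt²|² dt,     LDLJ = −ln|DLJ|.

With e = 3 the quantity is dimensionless for a speed input and invariant to
traversing the same path more slowly; e = 5 reproduces the formula as more
commonly printed and is available via `dlj_duration_exponent` (the two
coincide for movements of exactly unit duration). The log transform restores
sensitivity: raw DLJ spans orders of magnitude across the physiological
range. For the minimum-jerk profile the closed form is DLJ = −720/1.875² =
−204.8 independent of D and T, i.e. LDLJ = −5.322; the discretised
implementation reproduces this to ~0.6% at 100 Hz.

### Number of peaks (NP)

The negative count of strict interior local maxima of v(t) (endpoints never
count), via `scipy.signal.find_peaks`. With the default zero prominence
every ripple counts, which makes NP fragile under noise; a prominence
threshold (`np_min_prominence`, units of v) is available but off by default
since the defining equation carries none.

## Input transforms

Measures consume a nonnegative scalar profile. The transform depends on what
was measured:

| measured variable | spectral measures (SPARC/SAL) | jerk measures (DLJ/LDLJ) |
|---|---|---|
| position | speed ‖dx/dt‖ | speed ‖dx/dt‖ |
| 3-axis accelerometer | \| ‖a‖ − g \| (g default 9.81 m/s²) | jerk ‖da/dt‖ |
| force / torque | ‖dF/dt‖ | ‖d³F/dt³‖ |

The accelerometer rule assumes quasi-static gravity orientation; the
force/torque rules extrapolate "treat it like a position variable". Both are
heuristics from the assessment literature that have not been validated
experimentally — they are implemented as stated and should be treated as
experimental.

Differentiation uses `numpy.gradient` with second-order one-sided edge
stencils. The edge order matters: the minimum-jerk speed's second derivative
peaks at the movement boundaries, and first-order edges bias DLJ by ~8% at
100 Hz versus ~0.6% with second-order edges. Derivatives keep the sample
count of their source so segmentation boundaries remain aligned.
Derivative magnitudes below 1e−12·max|x|/dtᵒʳᵈᵉʳ are snapped to zero: these
are float round-off residuals of differentiating an exactly constant
stretch, and without snapping a pure dwell would pass the degenerate-input
guard and be scored on numerical noise.

An optional zero-phase Butterworth low-pass is provided but **off by
default**; if used, the identical filter must be applied to every compared
recording, since the same movement filtered differently yields different
smoothness estimates.

## Rhythmic movements: segmentation and overall smoothness

Applying a measure to an entire rhythmic recording conflates stroke
smoothness with the temporal organisation of strokes (movement time MT vs
dwell time DT, number of repetitions): the generator's M_a (10 back-and-forth
cycles, 1.25 s per half-cycle) and M_d (identical strokes, 20 cycles) differ
by ~0.9 in whole-trace SPARC and ~2.8 in whole-trace LDLJ despite identical
stroke quality. The framework instead:

1. partitions the recording at analyst-chosen boundary times t₁ < … <
   t_{N+1} into half-open components [tᵢ, tᵢ₊₁) that tile the span exactly
   (no sample dropped or duplicated);
2. scores each component with the chosen measure;
3. aggregates with the weighted average Λ = Σwᵢλᵢ / Σwᵢ, wᵢ ≥ 0, Σwᵢ ≠ 0.

The weighted average satisfies the three properties an overall-smoothness
aggregate needs — identical components give the common value; Λ is invariant
to component ordering; and Λ is bounded by the extreme weighted components.
Weight schemes shipped: uniform (default), odd-only / even-only (e.g. only
outbound strokes), duration-weighted, explicit vector. Zero-weight
components are still scored and reported so smoothness can be tracked event
by event; a component that is pure dwell (no movement) is degenerate and is
recorded as a per-component error — Λ is produced only if every weighted
component succeeded.

No canonical segmentation exists; boundaries are the analyst's choice guided
by task events, and the library never auto-segments silently. A
speed-threshold dwell detector (`detect_dwell_boundaries`: speed below a
fraction of v_peak for a minimum duration) is provided as a labelled
convenience only.

Task identity travels with each result (`task_label`); the CLI warns when
comparing reports with different labels, because normative smoothness levels
are task-dependent.

## The simulator

`simulate` generates the study conditions used throughout the tests:

* **Minimum-jerk reach** — v(τT) = (D/T)·30τ²(1−τ)², the canonical smooth
  movement; defaults D = 0.1 m, T = 1 s, fs = 100 Hz.
* **Submovement superpositions** — pointwise sums of minimum-jerk strokes at
  specified onsets; the "stroke-like" fixture is 3 submovements of D/3 with
  0.5 s gaps (three distinct speed peaks).
* **Rhythmic presets** — M_a (10 cycles, MT = 1.0 s, DT = 0.25 s), M_c
  (10 cycles, MT = 0.56 s, DT = 0.14 s — the same 4:1 MT:DT ratio, so each
  component is an exact time-scaled copy of M_a's), M_d (M_a's timing, 20
  cycles), M_b (M_a's timing with each stroke replaced by a 3-submovement
  superposition — the less smooth mover). Only the component time (MT+DT) of
  these scenarios is fixed by their boundary definitions; the MT/DT split and
  the M_b construction are this package's documented choices. Ground-truth
  segmentations are returned alongside the traces.
* **Noise** — additive Gaussian white noise with variance mean(v²)/SNR,
  seeded and reproducible. Noisy speed profiles are clipped at zero (a
  measured speed magnitude cannot be negative).

What the generator does *not* emulate: biomechanically realistic 2-D/3-D
paths, sensor drift or quantisation, non-minimum-jerk submovement shapes,
and physiological tremor spectra. Passing tests therefore demonstrate the
measures' mathematical properties under the idealised conditions, not
clinical validity on real recordings.

## Numerical choices

* **Spectrum**: real FFT of the profile zero-padded to
  `zero_padding_factor` (default 4) × the next power of two; frequency axis
  in rad/s up to Nyquist; normalisation by the DC bin.
* **Adaptive cutoff**: evaluated on the discrete grid — the last bin with
  V̂ ≥ V̄ (so a resurgent supra-threshold bump pushes the cutoff past
  itself), capped at ωc_max, never below the first nonzero bin.
* **Arc quadrature**: piecewise-linear summation over grid points in
  [0, ωc]. The integration endpoint is refined by linearly interpolating the
  exact threshold crossing between the cutoff bin and its successor (and,
  for SAL or a saturated cutoff, by interpolating the magnitude at ωc_max):
  bin-snapping the endpoint leaves a grid artefact of up to ~0.015 in SPARC
  at the default padding that decays only linearly with the padding factor,
  while endpoint interpolation reduces the worst temporal-scaling deviation
  over α ∈ [0.5, 2] to ~2e−3.
* **DLJ integration**: trapezoidal rule on the squared second derivative.
* **v_peak ties**: first occurrence (affects only the reported peak time).
* **Degenerate inputs**: an all-zero profile (fixed posture) is rejected by
  every measure — smoothness of no-movement is undefined, not zero.
* **Segment index arithmetic**: boundary-to-index division carries a
  1e−6-sample slack to absorb float error; components are half-open with the
  final sample of the span assigned to the last component.
* **Monotonicity flags** in the validity sweep use strict comparison with a
  1e−9 tolerance (noise-free data).

## Study harnesses and problem sizes

`evaluation` runs three studies, all reproducible from recorded seeds:
validity sweeps (submovement count 1–4, gaps 0.2–0.8 s, noise-free),
reliability sweeps (default 50 noise replicates per SNR on the reach
fixture), and the speed-bias study (duration scales at constant noise
power, where slower movements necessarily have lower SNR and noise-fragile
measures underestimate their smoothness). Cross-measure comparisons
normalise each measure's deviation by its own smooth-vs-intermittent
fixture gap, since SPARC (range ~1.4–4) and LDLJ (range ~5–12) scales
differ. Replicate counts of 20–50 keep every study in the seconds range at
100 Hz while leaving the reported orderings far from their decision
boundaries.

## Known limitations

* SPARC values retain a small grid dependence (~2e−3) from the discrete
  cutoff; comparisons should use identical `MeasureParams`.
* The DLJ/LDLJ of concatenated components is sensitive to the edge stencil
  at component boundaries; segment at genuine movement starts/ends (dwells),
  not mid-movement.
* NP with zero prominence is unusable on noisy data without low-pass
  filtering; this is a property of the measure, reproduced faithfully.
* The accelerometer transform degrades when sensor orientation changes
  rapidly relative to gravity.
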