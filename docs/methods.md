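# Methods

## Signal model and units

The package works on fixed-rate (default 100 Hz) six-axis IMU streams from
a module worn upright at the waist. Canonical units everywhere are mg for
acceleration, dps for angular rate, degrees for angles and Hz for rates;
thresholds are stored in mg even where they are conventionally quoted in g
(0.8 g ≡ 800 mg), so the configuration reads exactly like the deployed
firmware constants. The configured sensor full scales are ±8000 mg and
±500 dps; out-of-range samples are flagged by `ImuTrace.out_of_range_mask`
but never silently clipped — the caller decides.

Three derived channels drive every decision. The signal vector magnitudes
ASVM/GSVM collapse the tri-axial signals into orientation-free norms. The
axis inclinations (θ, ψ, φ) = atan(aᵢ/√(aⱼ²+aₖ²)) treat the accelerometer
as a tilt sensor: valid only quasi-statically, signed, each confined to
[−90°, +90°], with no quadrant disambiguation (a gravity-only accelerometer
cannot provide more). A zero horizontal component yields ±90° with the sign
of the numerator (`arctan2` convention); the exact zero vector raises an
error in the scalar API. Sensor fusion (gyro integration, complementary or
Kalman filtering) is deliberately out of scope: the algorithm's premise is
that tilt from raw gravity components is sufficient once the signal has
settled. ψ in the posture stage is computed on raw samples; no filtering is
applied anywhere (none is part of the algorithm).

Windowed statistics use 1-based inclusive sample ranges in all public
configuration ("samples 151–200"), converted to Python slices in exactly
one place (`features.one_based_slice`). Standard deviations use the
population divisor (1/N over the slice), matching the printed 1/50 form;
`calibrate` exposes `ddof` for the sample form but defaults to the same
convention.

## The detector

`DetectorConfig` defaults: trigger 800 mg, impact 1400 mg, σ_Acc 100 mg and
σ_Gyro 10 dps over window samples 151–200, |ψ̄| < 60° over samples
181–200, window 200 samples at 100 Hz.

Decisions that the state-machine description leaves open, resolved here:

- **ψ criterion is absolute** (`psi_abs=True`): the pass condition is
  |ψ̄| < 60°. Post-fall ψ̄ is observed on both sides of zero (−30° to
  +25°), so the signed form would pass any face-down fall trivially and
  the absolute form is the only operationally consistent reading. The
  signed form remains selectable.
- **The triggering sample is window sample 1 of 200.** Recording "begins"
  at the trigger; including the trigger sample is the simpler convention
  and shifts all windows by at most one sample.
- **Strict inequalities throughout** (< 800, > 1400, < 100, < 10, < 60):
  boundary values fail.
- **Re-triggering:** samples inside a fully evaluated window are consumed;
  the trigger search resumes at the first sample after it. This matches an
  MCU that blocks while buffering and prevents duplicate alerts from one
  fall. Additional sub-trigger samples inside an open window do not restart
  it. After a confirmed event the machine returns to idle immediately — no
  refractory period beyond the consumed window.
- **End of stream with an open window:** the window is discarded and a
  truncation notice logged; there is no partial evaluation.
- **Extended posture window:** `psi_slice` may extend beyond `window_len`
  (e.g. 181–400), the false-positive mitigation that trades 1–2 s of alert
  latency for a longer posture observation. The buffer then extends to the
  slice end, and a window that reaches the ψ stage consumes those extra
  samples. Stages are evaluated as soon as their samples are available, so
  a failure at an earlier stage still aborts at sample 200 with no added
  latency. (The config type nominally constrains slices to the window; the
  mitigation requires relaxing that, so slice ends beyond `window_len` are
  legal and the buffer requirement is `DetectorConfig.buffer_len`.)

Two implementations share the contract. `detect_stream` drives the
per-sample `FallDetector` — the shape firmware takes — and exposes stage
evaluation counters (`stage_evals`), per-window rejection states, and an
optional per-sample state log, so the short-circuit property is observable.
`detect_offline` is a vectorized brute-force scan written independently;
the suite asserts list equality between the two on over a thousand mixed
traces at multiple configurations, including bit-equality of the evidence
floats (both paths compute features through the same primitive functions on
identical values, so IEEE determinism carries the proof through).

## Threshold calibration

`calibrate` summarises per-trial statistics (troughs of the
loss-of-balance phase, peaks of the impact phase, extracted by
`extract_trough`/`extract_peak` over caller-supplied windows — the phases
are not segmented automatically) as a normal fit: mean, SD, mean ± 3·SD,
and the observed extremes. The deployed thresholds are rounded from these
bounds by judgment — widened for the trigger (653.12 → 800 mg, to avoid
false negatives from an over-strict gate), narrowed for the impact
(1528.72 → 1400 mg) — so the recommended threshold is an explicit caller
argument, recorded verbatim, never a hidden heuristic.

## The synthetic generator

The generator emulates signals at the level the algorithm sees them:
piecewise-parametric magnitude envelopes (constant, raised-cosine and
oscillatory segments) distributed across axes by a programmed ψ trajectory,
plus noise. It is specified by which detector conditions each label must
satisfy or violate, not by biomechanics.

Falls follow the four stages. Defaults: 1 s standing at 1000 mg; a 0.35 s
descent to a trough drawn from N(474.56, 59.52²) mg and resampled until
below 800 mg; a 0.12 s + 0.25 s impact spike to a peak from
N(2007.16, 159.48²) mg resampled until above 1400 mg (A2+A3 well inside
the 2 s bound enforced by `FallStageParams`); then 3.8 s of stillness with
the y-axis settled at a tilt drawn uniformly from [−30°, +25°], the
observed post-fall range. The y-axis tips from 90° to the settle value over
0.7 s starting at the trough, about the x-axis for forward/backward falls
and the z-axis for lateral ones, with the gyro carrying the corresponding
rate (≤ ~300 dps) plus a transient noise burst. Three exactness guarantees
make ground truth trustworthy in tests: the trough and peak samples are
written exactly (no noise in A2/A3); quiet-phase noise (3 mg, 0.5 dps) is
applied to the magnitude only, so the emitted ψ equals the programmed
trajectory to float precision; and gravity is distributed per that
trajectory, so the tilt recovered from the samples is the programmed one.

Daily activities, each defined by its contract with the cascade —
amplitudes are chosen with ≥5σ noise margins so the contracts hold for
every seed:

- walking / stepping / ordinary sit-down: oscillation or a gentle dip that
  never crosses 800 mg → no trigger;
- stairs up/down: periodic dips to ~720–750 mg (trigger) with maxima below
  ~1200 mg → impact stage fails;
- running: 3 Hz oscillation spanning 700–1700 mg → triggers and impacts,
  but the tail σ_Acc (~350 mg) fails the stabilisation stage;
- jumping and quick sit: fall-like dip + spike + quiet tail, but the final
  tilt stays at 88°/80° → posture stage fails;
- quick sit, lean-back variant: after sitting, ψ rotates to 35° just before
  the σ windows open, holds through the default ψ slice, and re-rights by
  ~2.6 s post-trigger. This is the one template built to fool the default
  detector (ψ̄ ≈ 35°), and the extended 181–400 slice rejects it
  (ψ̄ ≈ 69°).
- device-displacement fall variant (off by default): a real fall whose
  settle tilt is drawn at 65–85°, emulating a module that slipped during
  wear — the false-negative mode.

The corpus builder mirrors the study design: 15 subjects × (50 falls cycled
over four directions + 50 trials of each of eight activities) = 6750
traces, with fixed per-subject ±10% jitter on segment durations and noise
scales, a configurable fraction of limp/heavy fall styles (20% combined by
default), and opt-in adversarial fractions. Everything is derived from one
`SeedSequence`, so a corpus is reproducible byte for byte.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: soft-tissue and surface-dependent impact
dynamics, gait variability beyond sinusoids, sensor bias/drift and
quantisation, strap-coupling artefacts, and genuinely ambiguous activities.
Perfect sensitivity/specificity on the synthetic corpus demonstrates that
the detector implements its specification faithfully, not that it would
achieve those figures on participants; real deployments miss falls when
the device shifts (emulated only by the displacement flag) and false-alarm
on lean-back sits (emulated by the lean-back flag).

## Evaluation metrics

Scoring is per trial: a fall trial with ≥1 event is one TP regardless of
how many alerts it produced (extras are tallied as a multiple-alert
diagnostic); a non-fall trial with any event is an FP. Sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy (TP+TN)/total are kept
unrounded internally; display rounding is three decimals for fractions and
one for percentages. Per-activity counts are kept so the pooled TN is
computed, never assumed.

## Power model

A constant-current linear discharge, C_rem = C_init − I_dis·t, with
explicit depletion handling (a depleted-at time, never a negative
capacity), and endurance C_init/I_avg. No voltage-curve or Peukert
correction — the model is for comparing operating modes (72 / 20 / 5 mA
presets on the 2000 mAh pack), not battery chemistry.

## Numerical and interface choices

- Trace CSVs are written with `%.17g` floats and read with round-trip
  parsing, so write→read is lossless; an index-only mode synthesises
  timestamps at exact spacing from a declared rate. Foreign layouts are
  handled by an explicit column map, never guessed.
- Timestamp validation requires strict monotonicity and spacing within
  half a sample period of the declared rate.
- Detector determinism is bit-for-bit on evidence fields for a fixed trace
  and config.
- Problem sizes in the shipped suites: the round-trip test runs the full
  6750-trace corpus; oracle equivalence runs ~1000 mixed traces at two
  configurations; distribution checks use 2000 falls (3-standard-error
  bands). The acceptance script repeats the round trip, mitigation and
  equivalence experiments at the same sizes from a single seed.

## Known limitations

- The detector assumes the worn orientation (y-axis vertical when
  standing); a rotated mounting invalidates the ψ stage.
- Tilt from raw gravity components is meaningless during high dynamics;
  the algorithm only ever reads ψ after the stabilisation stages for this
  reason, and the generator respects the same assumption.
- The calibration module summarises distributions; choosing the final
  integer threshold remains a human decision by design.
- No transport/notification stack: confirmed events go to a pluggable
  callback (the CLI wires it to a log line).
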