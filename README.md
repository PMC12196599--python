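# fallfsm

Finite-state-machine fall detection for waist-worn six-axis IMU data.

Falls among the elderly are a leading cause of injury death, and the
detectors that work best in practice are the ones simple enough to run for
days on a microcontroller strapped to a belt. `fallfsm` implements such a
detector — a six-state cascade over 100 Hz accelerometer/gyroscope streams —
together with everything needed to study it without hardware or
participants: the threshold-calibration procedure, a seeded synthetic IMU
generator covering four fall directions and eight daily activities,
trial-level evaluation metrics, and a battery-endurance model. It is aimed
at wearable-sensing researchers and firmware engineers who want a tested,
reproducible reference of the algorithm on a desktop.

## The algorithm

All decisions are made on three derived channels of the six-axis sample
stream (acceleration in mg, angular rate in dps):

- the accelerometer signal vector magnitude
  `ASVM = √(ax² + ay² + az²)` and its gyroscope analogue `GSVM`;
- the inclination ψ of the device's y-axis to the horizontal plane,
  `ψ = atan( ay / √(az² + ax²) )` — about +90° standing upright, near 0°
  lying on the ground (the module is worn upright at the waist, so the
  y-axis is the body's vertical).

A fall produces a characteristic four-stage ASVM signature: quiet standing
near 1 g (A1), a weightlessness dip during loss of balance (A2), an impact
spike (A3), and stabilisation near 1 g in a lying posture (A4). The
detector walks a six-state machine over that signature:

| state | condition | meaning |
|---|---|---|
| S1 → S2 | `ASVM < 800 mg` | trigger: weightlessness dip; buffer 200 samples (2 s) |
| S2 → S3 | any buffered `ASVM > 1400 mg` | ground impact inside the window |
| S3 → S4 | `σ_Acc < 100 mg` over samples 151–200 | acceleration has settled |
| S4 → S5 | `σ_Gyro < 10 dps` over samples 151–200 | rotation has stopped |
| S5 → S6 | `|ψ̄| < 60°` over samples 181–200 | torso ended up near-horizontal |

Both standard deviations use the population divisor (1/50). Any failed
check aborts immediately — later features are never computed, like a
cascade classifier — which is what makes the algorithm cheap enough for an
MCU. S6 emits the alert and the machine returns to idle.

Thresholds come from a calibration procedure (`fallfsm.calibration`): fit a
normal distribution to per-trial ASVM troughs and peaks, report
mean ± 3·SD next to the observed extremes, and round by judgment
(653.12 mg → 800 mg for the trigger; 1528.72 mg → 1400 mg for the impact).

## A worked example

```python
from fallfsm import generate_fall, detect_stream

st = generate_fall("fall_left", seed=42)   # stand → dip → impact → lying
events = detect_stream(st.trace)
```

Running `python examples/01_detect_a_fall.py` prints:

```
trace: 550 samples at 100 Hz (5.49 s)
programmed trough 492.7 mg, peak 1841.3 mg, settle tilt 17.2 deg

fall confirmed at t = 1.15 s
  trigger sample : 115 (ASVM fell below 800 mg)
  impact sample  : 141 (ASVM above 1400 mg)
  sigma_acc      :   2.91 mg   (< 100 mg: settled)
  sigma_gyro     :   0.34 dps  (< 10 dps: settled)
  psi_bar        :  17.22 deg  (|.| < 60: lying down)
```

The event's evidence trail is exactly the five cascade conditions: the
trigger fired at the first sub-800 mg sample, an impact spike sat inside
the 2 s window, both tail standard deviations show the signal settled, and
the mean y-axis tilt of 17° says the wearer ended up lying down.

The other examples cover threshold calibration
(`02_calibrate_thresholds.py`), corpus-level evaluation including the
lean-back false-positive mitigation (`03_evaluate_corpus.py`), and battery
budgets (`04_power_budget.py`).

## Library layout

- `fallfsm.features` — SVMs, inclination angles, windowed statistics.
- `fallfsm.detector` — `DetectorConfig`, the streaming `FallDetector` /
  `detect_stream`, and the independent brute-force `detect_offline` oracle
  (both must agree on every input; the tests check this on >1000 traces).
- `fallfsm.calibration` — per-trial extrema and the mean ± 3·SD summary.
- `fallfsm.synthetic` — seeded fall/daily-activity generators and the
  corpus builder (15 subjects × 450 trials by default), including the
  adversarial variants (lean-back quick sit, device displacement).
- `fallfsm.metrics` — trial-level confusion counts, sensitivity,
  specificity, accuracy, per-activity breakdown.
- `fallfsm.power` — linear battery model and operating-mode presets.
- `fallfsm.io` / `fallfsm.cli` — trace CSV dialect, YAML/JSON config,
  event exports, and the `fallfsm` command
  (`simulate | detect | calibrate | evaluate | power`).

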