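"""Seeded synthetic six-axis IMU traces for falls and daily activities.

The generator replaces wearable hardware and participants in tests: it emits
labelled 100 Hz traces whose morphologies realise (or deliberately violate)
the detector's cascade conditions.

Falls follow the four-stage signal model: static standing (A1, ASVM ≈ 1 g,
y-axis vertical), loss of balance (A2, weightlessness dip below the trigger
level to a sampled trough), ground impact (A3, spike above the impact level
with direction-dependent axis loading), and stable recovery (A4, settling
back near 1 g with the y-axis now near-horizontal).  Trough and peak values
are drawn from the normal distributions fitted during calibration
(474.56 ± 59.52 mg and 2007.16 ± 159.48 mg) and written *exactly* into the
trace; noise is added only outside the defining samples, and in quiet
phases only along the signal magnitude so the emitted tilt angles are exact.

Daily activities are defined by which detector conditions they must satisfy
or violate: walking/stepping/sitting never reach the trigger; stair
descent/ascent triggers but shows no impact; running triggers and impacts
but keeps oscillating (large tail σ); jumping and quick sitting mimic a
fall's magnitude profile but end upright (ψ̄ ≈ 80–90°).  The
``quick_sit_leanback`` variant reproduces the known false-positive mode — a
brief backward lean drops ψ̄ below the threshold during the default
observation slice but recovers within 1–2 s, so an extended ψ slice
rejects it.

Morphologies are piecewise parametric (constant / raised-cosine segments
plus noise), not biomechanical simulation; each template is specified by the
threshold relations above, which the tests verify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Union

import numpy as np

from .features import ACC_FULL_SCALE_MG, ImuTrace

__all__ = [
    "ActivityLabel",
    "FALL_LABELS",
    "ADL_LABELS",
    "FallStageParams",
    "SyntheticTrace",
    "WrongGeneratorError",
    "generate_fall",
    "generate_adl",
    "generate_dataset",
    "iter_dataset",
]


class WrongGeneratorError(ValueError):
    """A fall label was passed to the ADL generator or vice versa."""


class ActivityLabel(str, Enum):
    """Ground-truth label: four fall directions and eight daily activities."""

    FALL_FORWARD = "fall_forward"
    FALL_BACKWARD = "fall_backward"
    FALL_LEFT = "fall_left"
    FALL_RIGHT = "fall_right"
    WALKING = "walking"
    RUNNING = "running"
    STEPPING = "stepping"
    UPSTAIRS = "upstairs"
    DOWNSTAIRS = "downstairs"
    JUMPING = "jumping"
    SIT_DOWN = "sit_down"
    QUICK_SIT = "quick_sit"


FALL_LABELS = frozenset({
    ActivityLabel.FALL_FORWARD, ActivityLabel.FALL_BACKWARD,
    ActivityLabel.FALL_LEFT, ActivityLabel.FALL_RIGHT,
})
ADL_LABELS = tuple(l for l in ActivityLabel if l not in FALL_LABELS)

# horizontal unit vector the y-axis tips toward, per fall direction
_FALL_AXIS = {
    ActivityLabel.FALL_FORWARD: (0.0, -1.0),
    ActivityLabel.FALL_BACKWARD: (0.0, 1.0),
    ActivityLabel.FALL_LEFT: (-1.0, 0.0),
    ActivityLabel.FALL_RIGHT: (1.0, 0.0),
}


@dataclass(frozen=True)
class FallStageParams:
    """Parameters of the four-stage fall template.

    Trough/peak moments default to the calibration-fit distributions; the
    post-fall ψ settle value is uniform on [post_psi_low, post_psi_high],
    the observed post-fall range.  Sampled troughs are resampled until below
    ``trigger_level`` and peaks until above ``impact_level``, so every
    default-parameter fall is a valid detector stimulus.  With
    ``device_displacement`` the settle ψ is drawn high (65–85°) instead,
    emulating a shifted/loose device — the known false-negative mode.
    """

    fs: float = 100.0
    a1_duration: float = 1.0            # s of quiet standing
    a2_duration: float = 0.35           # s, descent to the trough
    a3_rise_duration: float = 0.12      # s, trough -> impact peak
    a3_fall_duration: float = 0.25      # s, peak -> settle level
    rotation_duration: float = 0.70     # s, y-axis tips to its final tilt
    a4_duration: float = 3.80           # s of post-fall stillness
    base_mg: float = 1000.0
    trough_mean: float = 474.56
    trough_sd: float = 59.52
    peak_mean: float = 2007.16
    peak_sd: float = 159.48
    post_psi_low: float = -30.0
    post_psi_high: float = 25.0
    a2a3_max_duration: float = 2.0
    trigger_level: float = 800.0
    impact_level: float = 1400.0
    settle_noise_acc: float = 3.0       # mg, magnitude noise in A1/A4
    settle_noise_gyro: float = 0.5      # dps
    transient_noise_gyro: float = 4.0   # dps, extra gyro noise in A2/A3
    device_displacement: bool = False

    def __post_init__(self) -> None:
        for name in ("fs", "a1_duration", "a2_duration", "a3_rise_duration",
                     "a3_fall_duration", "rotation_duration", "a4_duration",
                     "trough_sd", "peak_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        a23 = self.a2_duration + self.a3_rise_duration + self.a3_fall_duration
        if a23 > self.a2a3_max_duration:
            raise ValueError(
                f"A2+A3 span {a23:.2f}s exceeds the {self.a2a3_max_duration}s "
                "fall-duration bound"
            )
        if not (0 < self.trigger_level < self.impact_level):
            raise ValueError("need 0 < trigger_level < impact_level")


@dataclass
class SyntheticTrace:
    """A generated trace with its label, variant and programmed ground truth.

    ``ground_truth`` holds the stage boundaries and the exactly-realised
    trough/peak/ψ values so tests can verify recovery without re-deriving
    them from the samples.
    """

    trace: ImuTrace
    label: ActivityLabel
    seed: int
    variant: Optional[str] = None
    subject: Optional[int] = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def is_fall(self) -> bool:
        return self.label in FALL_LABELS


# ---------------------------------------------------------------------------
# segment primitives
# ---------------------------------------------------------------------------

def _rc(v0: float, v1: float, n: int) -> np.ndarray:
    """Raised-cosine ramp from v0 to v1 over n samples (endpoints included)."""
    x = np.linspace(0.0, 1.0, n)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * x))


def _acc_from(mag: np.ndarray, psi_deg: np.ndarray,
              hx: float, hz: float) -> np.ndarray:
    """Distribute a magnitude envelope across axes per a ψ trajectory.

    The unit direction (hx·cosψ, sinψ, hz·cosψ) keeps the emitted tilt
    angle exactly the programmed ψ for any magnitude, so magnitude-only
    noise never perturbs the angle channel.
    """
    r = np.radians(psi_deg)
    u = np.stack([hx * np.cos(r), np.sin(r), hz * np.cos(r)], axis=1)
    return mag[:, None] * u


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      *, below: float = math.inf,
                      above: float = -math.inf) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if above < v < below:
            return float(v)
    raise RuntimeError(
        f"could not sample N({mean}, {sd}²) within ({above}, {below})"
    )


def _rng_and_seed(seed: Union[int, np.random.Generator]
                  ) -> tuple[np.random.Generator, int]:
    if isinstance(seed, np.random.Generator):
        sub = int(seed.integers(2 ** 31))
        return np.random.default_rng(sub), sub
    return np.random.default_rng(seed), int(seed)


# ---------------------------------------------------------------------------
# fall generator
# ---------------------------------------------------------------------------

def generate_fall(direction: Union[str, ActivityLabel],
                  params: Optional[FallStageParams] = None,
                  seed: Union[int, np.random.Generator] = 0,
                  variant: Optional[str] = None) -> SyntheticTrace:
    """Generate one four-stage fall trace.

    ``variant`` may be ``"limp"`` (slow, soft fall: trough and peak drawn
    near the permissive bounds) or ``"heavy"`` (deep trough, hard impact).
    The returned ground truth records stage boundaries, trigger index, and
    the exactly-realised trough/peak/settle-ψ values.
    """
    direction = ActivityLabel(direction)
    if direction not in FALL_LABELS:
        raise WrongGeneratorError(f"{direction} is not a fall direction")
    p = params or FallStageParams()
    if variant == "limp":
        p = replace(p, trough_mean=700.0, trough_sd=50.0,
                    peak_mean=1620.0, peak_sd=100.0)
    elif variant == "heavy":
        p = replace(p, trough_mean=350.0, trough_sd=50.0,
                    peak_mean=2400.0, peak_sd=150.0)
    elif variant is not None:
        raise ValueError(f"unknown fall variant {variant!r}")
    rng, used_seed = _rng_and_seed(seed)

    trough = _truncated_normal(rng, p.trough_mean, p.trough_sd,
                               below=p.trigger_level, above=1.0)
    peak = _truncated_normal(rng, p.peak_mean, p.peak_sd,
                             above=p.impact_level,
                             below=ACC_FULL_SCALE_MG * 0.9)
    if p.device_displacement:
        settle_psi = rng.uniform(65.0, 85.0)
    else:
        settle_psi = rng.uniform(p.post_psi_low, p.post_psi_high)

    fs = p.fs
    n1 = round(p.a1_duration * fs)
    n2 = max(4, round(p.a2_duration * fs))
    n3r = max(3, round(p.a3_rise_duration * fs))
    n3f = max(3, round(p.a3_fall_duration * fs))
    nrot = max(4, round(p.rotation_duration * fs))
    n4 = round(p.a4_duration * fs)

    mag = np.concatenate([
        np.full(n1, p.base_mg),
        _rc(p.base_mg, trough, n2),          # A2: trough exact at the end
        _rc(trough, peak, n3r)[1:],          # A3: peak exact at the end
        _rc(peak, p.base_mg, n3f)[1:],
        np.full(n4, p.base_mg),
    ])
    n = mag.shape[0]
    trough_idx = n1 + n2 - 1
    peak_idx = trough_idx + (n3r - 1)
    settle_idx = peak_idx + (n3f - 1)

    # y-axis tips from vertical to its settled tilt, starting at the trough
    psi = np.full(n, 90.0)
    rot_end = min(trough_idx + nrot, n)
    psi[trough_idx:rot_end] = _rc(90.0, settle_psi, rot_end - trough_idx)
    psi[rot_end:] = settle_psi

    # noise: magnitude-only, and only outside the defining A2/A3 samples
    quiet = np.zeros(n, dtype=bool)
    quiet[:n1] = True
    quiet[max(settle_idx, rot_end):] = True
    mag = mag + rng.normal(0.0, p.settle_noise_acc, n) * quiet

    hx, hz = _FALL_AXIS[direction]
    acc = _acc_from(mag, psi, hx, hz)

    # gyro: the rotation rate on the tipping axis plus a transient burst
    rate = np.gradient(psi) * fs                       # deg/s
    gyro = rng.normal(0.0, p.settle_noise_gyro, (n, 3))
    active = ~quiet
    gyro[active] += rng.normal(0.0, p.transient_noise_gyro,
                               (int(active.sum()), 3))
    rot_axis = 0 if hz != 0.0 else 2   # forward/backward tip about x, lateral about z
    gyro[:, rot_axis] += rate

    trace = ImuTrace.from_arrays(acc, gyro, fs=fs)
    env_trigger = int(np.argmax(mag[n1:n1 + n2] < p.trigger_level) + n1)
    gt = {
        "trough": trough,
        "trough_index": trough_idx,
        "peak": peak,
        "peak_index": peak_idx,
        "settle_psi": settle_psi,
        "trigger_index": env_trigger,
        "a2_start": n1,
        "a3_start": trough_idx + 1,
        "a4_start": settle_idx,
    }
    return SyntheticTrace(trace=trace, label=direction, seed=used_seed,
                          variant=variant, ground_truth=gt)


# ---------------------------------------------------------------------------
# daily-activity generator
# ---------------------------------------------------------------------------

def generate_adl(label: Union[str, ActivityLabel],
                 seed: Union[int, np.random.Generator] = 0,
                 duration: float = 5.0,
                 *, fs: float = 100.0,
                 noise_scale: float = 1.0,
                 tempo: float = 1.0,
                 variant: Optional[str] = None) -> SyntheticTrace:
    """Generate one daily-activity trace of ``duration`` seconds.

    ``variant="leanback"`` is only valid for ``quick_sit`` and produces the
    false-positive morphology (transient backward lean after sitting).
    """
    label = ActivityLabel(label)
    if label in FALL_LABELS:
        raise WrongGeneratorError(
            f"{label} is a fall; use generate_fall instead"
        )
    if variant not in (None, "leanback"):
        raise ValueError(f"unknown ADL variant {variant!r}")
    if variant == "leanback" and label is not ActivityLabel.QUICK_SIT:
        raise ValueError("the leanback variant applies to quick_sit only")
    rng, used_seed = _rng_and_seed(seed)
    n = round(duration * fs)
    t = np.arange(n) / fs
    base = 1000.0
    psi = np.full(n, 90.0)
    mag_noise = np.zeros(n)
    gyro = rng.normal(0.0, 0.5 * noise_scale, (n, 3))
    hx, hz = 0.0, 1.0
    gt: dict = {}

    def osc(amp: float, freq: float, phase: float) -> np.ndarray:
        return amp * np.sin(2 * np.pi * freq * tempo * t + phase)

    if label in (ActivityLabel.WALKING, ActivityLabel.STEPPING):
        amp, freq = (130.0, 1.8) if label is ActivityLabel.WALKING else (110.0, 2.2)
        phase = rng.uniform(0, 2 * np.pi)
        mag = base + osc(amp, freq, phase)
        mag_noise[:] = 8.0
        gyro[:, 0] += osc(30.0, freq, phase)
        gyro[:, 2] += osc(15.0, freq, phase + 1.0)
    elif label is ActivityLabel.RUNNING:
        # dips below the trigger and spikes past the impact level every
        # stride; the sustained oscillation keeps the tail σ far above the
        # stabilisation thresholds
        phase = rng.uniform(0, 2 * np.pi)
        mag = 1200.0 + osc(500.0, 3.0, phase)
        mag_noise[:] = 15.0
        gyro[:, 0] += osc(120.0, 3.0, phase)
        gyro[:, 1] += osc(60.0, 3.0, phase + 0.7)
    elif label in (ActivityLabel.UPSTAIRS, ActivityLabel.DOWNSTAIRS):
        # reaches the trigger on each step but never the impact level
        if label is ActivityLabel.UPSTAIRS:
            mid, amp, freq = 950.0, 200.0, 1.2
        else:
            mid, amp, freq = 940.0, 220.0, 1.4
        mag = mid + osc(amp, freq, rng.uniform(0, 2 * np.pi))
        mag_noise[:] = 8.0
        gyro[:, 0] += osc(40.0, freq, rng.uniform(0, 2 * np.pi))
    elif label is ActivityLabel.SIT_DOWN:
        mag, psi, gyro_extra, gt = _sit_down_profile(n, fs, tempo)
        gyro[:, 0] += gyro_extra
        mag_noise[:] = 3.0
    elif label is ActivityLabel.JUMPING:
        mag, psi, gyro_extra, gt = _jump_profile(n, fs, tempo, rng)
        gyro[:, 0] += gyro_extra
        mag_noise[:] = 3.0
        hz = -1.0
    else:  # quick_sit
        mag, psi, gyro_extra, gt = _quick_sit_profile(
            n, fs, tempo, rng, leanback=(variant == "leanback"))
        gyro[:, 0] += gyro_extra
        mag_noise[:] = 3.0

    mag = mag + rng.normal(0.0, 1.0, n) * mag_noise * noise_scale
    acc = _acc_from(mag, psi, hx, hz)
    trace = ImuTrace.from_arrays(acc, gyro, fs=fs)
    return SyntheticTrace(trace=trace, label=label, seed=used_seed,
                          variant=variant, ground_truth=gt)


def _sit_down_profile(n: int, fs: float, tempo: float):
    """Ordinary sit-down: gentle dip, soft landing, ends seated upright."""
    n1 = round(1.0 * fs * tempo)
    nd = round(0.5 * fs * tempo)
    nu = round(0.3 * fs * tempo)
    ns = round(0.4 * fs * tempo)
    mag = np.full(n, 1000.0)
    seg = np.concatenate([_rc(1000, 880, nd), _rc(880, 1120, nu)[1:],
                          _rc(1120, 1000, ns)[1:]])
    end = min(n1 + seg.shape[0], n)
    mag[n1:end] = seg[:end - n1]
    psi = np.full(n, 90.0)
    rot0, rot1 = n1, min(n1 + nd + nu, n)
    psi[rot0:rot1] = _rc(90.0, 80.0, rot1 - rot0)
    psi[rot1:] = 80.0
    gyro_extra = np.zeros(n)
    gyro_extra[rot0:rot1] = np.gradient(psi[rot0:rot1]) * fs
    return mag, psi, gyro_extra, {"action_start": n1}


def _jump_profile(n: int, fs: float, tempo: float, rng: np.random.Generator):
    """Jump: take-off dip, landing spike, decaying ring-down, ends upright."""
    n1 = round(0.7 * fs * tempo)
    nd = round(0.25 * fs * tempo)   # descent into weightlessness
    nh = round(0.10 * fs * tempo)   # flight
    nr = round(0.10 * fs * tempo)   # landing rise
    low = rng.uniform(500.0, 620.0)
    peak = rng.uniform(1750.0, 2050.0)
    mag = np.full(n, 1000.0)
    seg = np.concatenate([
        _rc(1000, low, nd), np.full(nh, low), _rc(low, peak, nr)[1:],
    ])
    end = min(n1 + seg.shape[0], n)
    mag[n1:end] = seg[:end - n1]
    # ring-down: decaying oscillation around 1 g for ~0.5 s after landing
    nring = round(0.5 * fs * tempo)
    i0, i1 = end, min(end + nring, n)
    tt = np.arange(i1 - i0) / fs
    mag[i0:i1] = 1000.0 + (peak - 1000.0) * np.exp(-tt / 0.08) * np.cos(
        2 * np.pi * 6.0 * tt)
    psi = np.full(n, 90.0)
    # brief crouch tilt during the action; upright well before the ψ window
    psi[n1:end] = 78.0
    psi[end:i1] = _rc(78.0, 88.0, i1 - end)
    psi[i1:] = 88.0
    gyro_extra = np.zeros(n)
    gyro_extra[n1:i1] = rng.normal(0.0, 60.0, i1 - n1)
    return mag, psi, gyro_extra, {"action_start": n1, "peak_index": end - 1}


def _quick_sit_profile(n: int, fs: float, tempo: float,
                       rng: np.random.Generator, leanback: bool):
    """Quick sit: fall-like magnitude profile that ends seated upright.

    With ``leanback`` the subject tips backward after landing (ψ dips to
    ~35° through the default ψ window) and re-rights within ~1 s, the
    false-positive mode that an extended ψ window filters out.
    """
    n1 = round(0.55 * fs * tempo)
    nd = round(0.25 * fs * tempo)
    nr = round(0.10 * fs * tempo)
    nf = round(0.30 * fs * tempo)
    low = rng.uniform(560.0, 660.0)
    peak = rng.uniform(1480.0, 1750.0)
    mag = np.full(n, 1000.0)
    seg = np.concatenate([
        _rc(1000, low, nd), _rc(low, peak, nr)[1:], _rc(peak, 1000, nf)[1:],
    ])
    end = min(n1 + seg.shape[0], n)
    mag[n1:end] = seg[:end - n1]

    # trigger sample of the deterministic envelope (noise is small)
    i0 = n1 + int(np.argmax(seg < 800.0))
    psi = np.full(n, 90.0)
    s0, s1 = n1 + nd // 2, min(end + nr, n)
    psi[s0:s1] = _rc(90.0, 80.0, s1 - s0)
    psi[s1:] = 80.0
    gyro_extra = np.zeros(n)
    gyro_extra[n1:end] = rng.normal(0.0, 40.0, end - n1)
    gt = {"action_start": n1, "trigger_index": i0}
    if leanback:
        # lean: rotate 80 -> 35 just before the σ windows open, hold through
        # the default ψ slice, re-right before sample 300 post-trigger
        marks = [(105, 143, 80.0, 35.0), (235, 265, 35.0, 85.0)]
        for (r0, r1, v0, v1) in marks:
            j0, j1 = min(i0 + r0, n), min(i0 + r1, n)
            if j1 > j0:
                psi[j0:j1] = _rc(v0, v1, j1 - j0)
            psi[j1:] = v1
        rate = np.gradient(psi) * fs
        gyro_extra = gyro_extra + rate
        gt["lean_psi"] = 35.0
    return mag, psi, gyro_extra, gt


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def iter_dataset(n_subjects: int = 15, falls_per_subject: int = 50,
                 adl_per_activity: int = 50, seed: int = 0,
                 *, leanback_fraction: float = 0.0,
                 displacement_fraction: float = 0.0,
                 fall_variant_fraction: float = 0.2
                 ) -> Iterator[SyntheticTrace]:
    """Lazily generate the labelled study corpus.

    Per subject: ``falls_per_subject`` falls cycled over the four
    directions, then ``adl_per_activity`` trials of each of the eight
    daily activities (defaults: 15 × (50 + 8·50) = 6750 traces).  Subjects
    carry fixed ±10% jitter on segment durations and noise scales.
    ``leanback_fraction`` of quick-sit trials use the lean-back variant;
    ``displacement_fraction`` of falls use the device-displacement
    (false-negative) variant; ``fall_variant_fraction`` of falls are split
    between limp and heavy styles.  Deterministic under a fixed seed.
    """
    if min(n_subjects, falls_per_subject, adl_per_activity) < 0:
        raise ValueError("counts must be non-negative")
    root = np.random.SeedSequence(seed)
    directions = sorted(FALL_LABELS, key=lambda l: l.value)
    for subj, subj_ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(subj_ss)
        tempo = float(rng.uniform(0.9, 1.1))
        noise_scale = float(rng.uniform(0.9, 1.1))
        base_params = FallStageParams(
            a1_duration=1.0 * tempo,
            a2_duration=0.35 * tempo,
            a3_rise_duration=0.12 * tempo,
            a3_fall_duration=0.25 * tempo,
            rotation_duration=0.70 * tempo,
            settle_noise_acc=3.0 * noise_scale,
            settle_noise_gyro=0.5 * noise_scale,
        )
        for k in range(falls_per_subject):
            direction = directions[k % 4]
            u = rng.random()
            if rng.random() < displacement_fraction:
                params, variant = replace(base_params,
                                          device_displacement=True), None
            elif u < fall_variant_fraction / 2:
                params, variant = base_params, "limp"
            elif u < fall_variant_fraction:
                params, variant = base_params, "heavy"
            else:
                params, variant = base_params, None
            st = generate_fall(direction, params, seed=rng, variant=variant)
            st.subject = subj
            yield st
        for label in ADL_LABELS:
            for _ in range(adl_per_activity):
                variant = None
                if (label is ActivityLabel.QUICK_SIT
                        and rng.random() < leanback_fraction):
                    variant = "leanback"
                st = generate_adl(label, seed=rng, tempo=tempo,
                                  noise_scale=noise_scale, variant=variant)
                st.subject = subj
                yield st


def generate_dataset(n_subjects: int = 15, falls_per_subject: int = 50,
                     adl_per_activity: int = 50, seed: int = 0,
                     **kwargs) -> list[SyntheticTrace]:
    """Materialised form of :func:`iter_dataset`."""
    return list(iter_dataset(n_subjects, falls_per_subject,
                             adl_per_activity, seed, **kwargs))
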