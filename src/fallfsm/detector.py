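"""Six-state finite-state-machine fall detector.

The detector watches the accelerometer signal vector magnitude (ASVM) of a
waist-worn IMU.  A drop below the trigger threshold (weightlessness during
loss of balance) opens a fixed-length evaluation window; the machine then
checks, in order and with short-circuit semantics,

1. **impact** — any window sample's ASVM above the impact threshold,
2. **σAcc**  — the ASVM settled (small population SD over the tail slice),
3. **σGyro** — the GSVM settled likewise,
4. **ψ̄**    — the mean y-axis inclination over the final slice is small,
   i.e. the torso ended up near-horizontal.

Only when every stage passes is a :class:`FallEvent` emitted; any failed
stage aborts immediately without computing later features, exactly like a
cascade classifier, and the machine returns to idle.

Two equivalent implementations are provided: :func:`detect_stream` drives a
per-sample :class:`FallDetector` (the shape an MCU firmware loop would
take), while :func:`detect_offline` is a brute-force vectorized scan kept
deliberately independent so the two can cross-check each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np

from .features import (
    ImuSample,
    ImuTrace,
    WindowFeatures,
    one_based_slice,
    psi_from_components,
)

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "TriggerWindow",
    "FallEvent",
    "FallDetector",
    "StreamError",
    "detect_stream",
    "detect_offline",
]

logger = logging.getLogger(__name__)


class StreamError(ValueError):
    """Samples arrived out of time order."""


class DetectorState(Enum):
    """The six FSM states.

    S1 idles until the ASVM trigger; S2 buffers the evaluation window and
    checks the impact criterion; S3–S5 check σAcc, σGyro and ψ̄; S6 signals
    a confirmed fall before the machine returns to S1.
    """

    S1_IDLE = 1
    S2_COLLECT = 2
    S3_SIGMA_ACC = 3
    S4_SIGMA_GYRO = 4
    S5_PSI = 5
    S6_ALERT = 6


@dataclass(frozen=True)
class DetectorConfig:
    """Every threshold and window length of the detector, in one place.

    Defaults are the deployed values: trigger at 800 mg, impact at 1400 mg,
    stabilisation thresholds 100 mg / 10 dps on the 50-point tail slice
    (window samples 151–200, 1-based), posture threshold |ψ̄| < 60° over
    samples 181–200, all at 100 Hz with a 200-sample window.

    ``psi_slice`` may extend beyond ``window_len`` (e.g. (181, 400)): the
    false-positive mitigation that trades 1–2 s of alert latency for a
    longer posture observation.  The detector then keeps buffering until the
    extended slice is available before deciding the ψ stage.

    ``psi_abs`` selects |ψ̄| < psi_thresh (default) rather than the signed
    form ψ̄ < psi_thresh; post-fall ψ̄ is observed on both sides of zero, so
    the absolute form is the operationally meaningful one.
    """

    fs: float = 100.0
    trigger_thresh: float = 800.0
    impact_thresh: float = 1400.0
    sigma_acc_thresh: float = 100.0
    sigma_gyro_thresh: float = 10.0
    psi_thresh: float = 60.0
    window_len: int = 200
    std_slice: tuple[int, int] = (151, 200)
    psi_slice: tuple[int, int] = (181, 200)
    psi_abs: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0 < self.trigger_thresh < self.impact_thresh):
            raise ValueError(
                "need 0 < trigger_thresh < impact_thresh; got "
                f"{self.trigger_thresh} / {self.impact_thresh}"
            )
        for name in ("sigma_acc_thresh", "sigma_gyro_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.psi_thresh <= 90):
            raise ValueError("psi_thresh must lie in (0, 90]")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        for name in ("std_slice", "psi_slice"):
            start, stop = getattr(self, name)
            if start < 1 or stop < start:
                raise ValueError(f"{name} must be a 1-based range with "
                                 "stop >= start >= 1")

    # cumulative sample counts at which each stage becomes decidable
    @property
    def need_impact(self) -> int:
        return self.window_len

    @property
    def need_sigma(self) -> int:
        return max(self.window_len, self.std_slice[1])

    @property
    def need_psi(self) -> int:
        return max(self.need_sigma, self.psi_slice[1])

    @property
    def buffer_len(self) -> int:
        """Samples buffered per trigger before the final stage can decide."""
        return self.need_psi


@dataclass(frozen=True)
class FallEvent:
    """A confirmed detection with its evidence trail.

    All feature fields satisfied their stage conditions by construction —
    an event only exists when every stage passed.
    """

    trigger_index: int
    impact_index: int
    sigma_acc: float
    sigma_gyro: float
    psi_bar: float
    trigger_time: float
    confirmed: bool = True

    def to_dict(self) -> dict:
        return {
            "trigger_time": self.trigger_time,
            "trigger_index": self.trigger_index,
            "impact_index": self.impact_index,
            "sigma_acc": self.sigma_acc,
            "sigma_gyro": self.sigma_gyro,
            "psi_bar": self.psi_bar,
        }


@dataclass
class TriggerWindow:
    """The buffered post-trigger window and its derived features."""

    start_index: int
    asvm_series: np.ndarray
    gsvm_series: np.ndarray
    psi_series: np.ndarray
    features: Optional[WindowFeatures]
    impact_found: bool
    impact_index: Optional[int]


# stage order of the cascade; the value is the state logged when the stage
# is the one that decides (fails, or for "psi" passes into S6)
_STAGES = ("impact", "sigma_acc", "sigma_gyro", "psi")
_STAGE_STATE = {
    "impact": DetectorState.S2_COLLECT,
    "sigma_acc": DetectorState.S3_SIGMA_ACC,
    "sigma_gyro": DetectorState.S4_SIGMA_GYRO,
    "psi": DetectorState.S5_PSI,
}


class FallDetector:
    """Streaming per-sample detector.

    Feed samples in time order with :meth:`step`; each call returns a
    :class:`FallEvent` when that sample completed a confirmed detection,
    else ``None``.  Call :meth:`finalize` at end of stream: an open,
    incomplete window is discarded with a truncation notice.

    ``stage_evals`` counts how often each cascade stage was actually
    evaluated — the short-circuit property is observable, not just claimed.
    ``rejections`` records (trigger_index, failing state) per aborted window.
    """

    def __init__(self, config: Optional[DetectorConfig] = None, *,
                 keep_state_log: bool = False,
                 on_event: Optional[Callable[[FallEvent], None]] = None):
        self.config = config or DetectorConfig()
        self.on_event = on_event
        self.events: list[FallEvent] = []
        self.state_log: Optional[list[DetectorState]] = (
            [] if keep_state_log else None
        )
        self.stage_evals = {s: 0 for s in _STAGES}
        self.rejections: list[tuple[int, DetectorState]] = []
        self.truncated = False
        self._index = 0
        self._last_t = -math.inf
        c = self.config
        self._needs = (c.need_impact, c.need_sigma, c.need_sigma, c.need_psi)
        self._std_sl = one_based_slice(c.std_slice)
        self._psi_sl = one_based_slice(c.psi_slice)
        self._reset_window()

    # -- internals ---------------------------------------------------------

    def _reset_window(self) -> None:
        self._state = DetectorState.S1_IDLE
        self._stage = 0
        self._start_index = -1
        self._start_time = 0.0
        self._asvm_buf: list[float] = []
        self._gsvm_buf: list[float] = []
        self._acc_buf: list[tuple[float, float, float]] = []
        self._impact_index: Optional[int] = None
        self._sigma_acc = math.nan
        self._sigma_gyro = math.nan

    @property
    def state(self) -> DetectorState:
        return self._state

    # -- public API ----------------------------------------------------------

    def step(self, sample: ImuSample) -> Optional[FallEvent]:
        """Advance the machine by one sample; return an event if confirmed."""
        t = float(sample.t)
        if t <= self._last_t:
            raise StreamError(
                f"non-monotone timestamp {t} after {self._last_t}"
            )
        self._last_t = t
        ax, ay, az = float(sample.ax), float(sample.ay), float(sample.az)
        gx, gy, gz = float(sample.gx), float(sample.gy), float(sample.gz)
        a = math.sqrt(ax * ax + ay * ay + az * az)

        event: Optional[FallEvent] = None
        tick_state = DetectorState.S1_IDLE
        if self._state is DetectorState.S1_IDLE:
            if a < self.config.trigger_thresh:
                # the triggering sample is window sample 1
                self._state = DetectorState.S2_COLLECT
                self._start_index = self._index
                self._start_time = t
        if self._state is not DetectorState.S1_IDLE:
            g = math.sqrt(gx * gx + gy * gy + gz * gz)
            self._asvm_buf.append(a)
            self._gsvm_buf.append(g)
            self._acc_buf.append((ax, ay, az))
            event, tick_state = self._advance_stages()

        if self.state_log is not None:
            self.state_log.append(tick_state)
        self._index += 1
        return event

    def finalize(self) -> None:
        """Signal end of stream; discard (and log) an open window."""
        if self._state is not DetectorState.S1_IDLE:
            self.truncated = True
            logger.warning(
                "stream ended with an open window (trigger at sample %d, "
                "%d of %d samples buffered); window discarded",
                self._start_index, len(self._asvm_buf), self.config.buffer_len,
            )
            self._reset_window()

    # -- cascade evaluation ------------------------------------------------

    def _advance_stages(self) -> tuple[Optional[FallEvent], DetectorState]:
        """Evaluate every stage whose samples are available; short-circuit.

        Once the window holds enough samples, the remaining stages resolve
        within the same tick (they consume no further input), so a failed
        check aborts without computing later features.
        """
        fill = len(self._asvm_buf)
        while self._stage < len(_STAGES) and fill >= self._needs[self._stage]:
            name = _STAGES[self._stage]
            self.stage_evals[name] += 1
            if name == "impact":
                ok = self._eval_impact()
            elif name == "sigma_acc":
                self._sigma_acc = float(
                    np.asarray(self._asvm_buf)[self._std_sl].std(ddof=0)
                )
                ok = self._sigma_acc < self.config.sigma_acc_thresh
            elif name == "sigma_gyro":
                self._sigma_gyro = float(
                    np.asarray(self._gsvm_buf)[self._std_sl].std(ddof=0)
                )
                ok = self._sigma_gyro < self.config.sigma_gyro_thresh
            else:  # psi
                return self._eval_psi()
            if not ok:
                state = _STAGE_STATE[name]
                self.rejections.append((self._start_index, state))
                self._reset_window()
                return None, state
            self._stage += 1
        return None, DetectorState.S2_COLLECT

    def _eval_impact(self) -> bool:
        imp = self.config.impact_thresh
        for i in range(self.config.window_len):
            if self._asvm_buf[i] > imp:
                self._impact_index = self._start_index + i
                return True
        return False

    def _eval_psi(self) -> tuple[Optional[FallEvent], DetectorState]:
        acc = np.asarray(self._acc_buf)
        psi = psi_from_components(acc[:, 0], acc[:, 1], acc[:, 2])
        psi_bar = float(psi[self._psi_sl].mean())
        crit = abs(psi_bar) if self.config.psi_abs else psi_bar
        if crit < self.config.psi_thresh:
            event = FallEvent(
                trigger_index=self._start_index,
                impact_index=self._impact_index,
                sigma_acc=self._sigma_acc,
                sigma_gyro=self._sigma_gyro,
                psi_bar=psi_bar,
                trigger_time=self._start_time,
            )
            self.events.append(event)
            logger.info("fall event confirmed: %s", event.to_dict())
            if self.on_event is not None:
                self.on_event(event)
            self._reset_window()
            return event, DetectorState.S6_ALERT
        self.rejections.append((self._start_index, DetectorState.S5_PSI))
        self._reset_window()
        return None, DetectorState.S5_PSI


def step(detector: FallDetector, sample: ImuSample) -> Optional[FallEvent]:
    """Functional alias for :meth:`FallDetector.step`."""
    return detector.step(sample)


def detect_stream(trace: ImuTrace, config: Optional[DetectorConfig] = None,
                  *, verbose: bool = False,
                  on_event: Optional[Callable[[FallEvent], None]] = None):
    """Run the streaming FSM over a whole trace.

    Returns the list of confirmed :class:`FallEvent`; with ``verbose=True``
    returns ``(events, state_log)`` where the log holds one
    :class:`DetectorState` per sample (the deepest state reached on that
    tick).  Deterministic: identical trace + config give an identical event
    list, bit for bit on the evidence fields.
    """
    det = FallDetector(config, keep_state_log=verbose, on_event=on_event)
    t = trace.t
    acc = trace.acc
    gyro = trace.gyro
    for i in range(len(trace)):
        det.step(ImuSample(t[i], acc[i, 0], acc[i, 1], acc[i, 2],
                           gyro[i, 0], gyro[i, 1], gyro[i, 2]))
    det.finalize()
    if verbose:
        return det.events, det.state_log
    return det.events


def detect_offline(trace: ImuTrace,
                   config: Optional[DetectorConfig] = None) -> list[FallEvent]:
    """Brute-force batch detector, the cross-check oracle.

    Scans every sample; at each sub-trigger ASVM not inside an already
    consumed window it evaluates the cascade conditions directly on array
    slices.  Independent of :class:`FallDetector` by construction, but must
    return an identical event list on every input:

    * a failed stage consumes exactly the samples buffered up to that
      stage's decision point (trigger search resumes right after),
    * a window truncated by end of stream yields no event and, since the
      stream detector would still be collecting, ends the scan.
    """
    cfg = config or DetectorConfig()
    a = trace.asvm()
    g = trace.gsvm()
    psi = trace.psi()
    std_sl = one_based_slice(cfg.std_slice)
    psi_sl = one_based_slice(cfg.psi_slice)
    n = len(trace)
    events: list[FallEvent] = []
    i = 0
    while i < n:
        if not a[i] < cfg.trigger_thresh:
            i += 1
            continue
        if i + cfg.need_impact > n:
            break  # truncated window swallows the rest of the stream
        win_a = a[i:i + cfg.window_len]
        hits = np.flatnonzero(win_a > cfg.impact_thresh)
        if hits.size == 0:
            i += cfg.need_impact
            continue
        if i + cfg.need_sigma > n:
            break
        sigma_acc = float(a[i + std_sl.start:i + std_sl.stop].std(ddof=0))
        if not sigma_acc < cfg.sigma_acc_thresh:
            i += cfg.need_sigma
            continue
        sigma_gyro = float(g[i + std_sl.start:i + std_sl.stop].std(ddof=0))
        if not sigma_gyro < cfg.sigma_gyro_thresh:
            i += cfg.need_sigma
            continue
        if i + cfg.need_psi > n:
            break
        psi_bar = float(psi[i + psi_sl.start:i + psi_sl.stop].mean())
        crit = abs(psi_bar) if cfg.psi_abs else psi_bar
        if crit < cfg.psi_thresh:
            events.append(FallEvent(
                trigger_index=i,
                impact_index=i + int(hits[0]),
                sigma_acc=sigma_acc,
                sigma_gyro=sigma_gyro,
                psi_bar=psi_bar,
                trigger_time=float(trace.t[i]),
            ))
        i += cfg.need_psi
    return events
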