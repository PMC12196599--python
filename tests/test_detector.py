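import dataclasses

import numpy as np
import pytest
from conftest import make_trace

from fallfsm import (
    DetectorConfig,
    DetectorState,
    FallDetector,
    ImuSample,
    ImuTrace,
    detect_offline,
    detect_stream,
    generate_adl,
    generate_fall,
    iter_dataset,
)
from fallfsm.detector import StreamError


class TestConfigValidation:
    def test_defaults_are_the_deployed_thresholds(self):
        c = DetectorConfig()
        assert (c.trigger_thresh, c.impact_thresh) == (800, 1400)
        assert (c.sigma_acc_thresh, c.sigma_gyro_thresh) == (100, 10)
        assert (c.psi_thresh, c.window_len) == (60, 200)
        assert c.std_slice == (151, 200) and c.psi_slice == (181, 200)

    @pytest.mark.parametrize("kwargs", [
        {"trigger_thresh": 1500, "impact_thresh": 1400},
        {"trigger_thresh": -1},
        {"psi_thresh": 0},
        {"psi_thresh": 91},
        {"sigma_acc_thresh": 0},
        {"std_slice": (0, 50)},
        {"psi_slice": (20, 10)},
        {"window_len": 0},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectorConfig(**kwargs)

    def test_extended_psi_window_lengthens_buffer(self):
        c = DetectorConfig(psi_slice=(181, 400))
        assert c.buffer_len == 400


class TestStreamingDetector:
    def test_quiet_standing_never_leaves_idle(self, quiet_trace):
        events, log = detect_stream(quiet_trace, verbose=True)
        assert events == []
        assert set(log) == {DetectorState.S1_IDLE}

    def test_canonical_fall_detected_once(self, canonical_fall):
        trace = canonical_fall.trace
        events = detect_stream(trace)
        assert len(events) == 1
        ev = events[0]
        first_sub = int(np.argmax(trace.asvm() < 800))
        assert ev.trigger_index == first_sub
        assert ev.trigger_time == pytest.approx(trace.t[first_sub])
        assert trace.asvm()[ev.impact_index] > 1400

    def test_event_evidence_satisfies_all_conditions(self, canonical_fall):
        # soundness: re-check every stage condition from the raw trace
        trace = canonical_fall.trace
        cfg = DetectorConfig()
        for ev in detect_stream(trace, cfg):
            i = ev.trigger_index
            a = trace.asvm()
            assert a[i] < cfg.trigger_thresh
            win = a[i:i + cfg.window_len]
            assert win.max() > cfg.impact_thresh
            assert ev.sigma_acc < cfg.sigma_acc_thresh
            assert ev.sigma_gyro < cfg.sigma_gyro_thresh
            assert abs(ev.psi_bar) < cfg.psi_thresh
            # recomputed features agree with the evidence trail
            assert a[i + 150:i + 200].std() == pytest.approx(ev.sigma_acc)
            assert trace.psi()[i + 180:i + 200].mean() == pytest.approx(
                ev.psi_bar)

    def test_quick_sit_rejected_at_posture_stage(self):
        st = generate_adl("quick_sit", seed=5)
        det = FallDetector()
        for s in st.trace:
            det.step(s)
        det.finalize()
        assert det.events == []
        assert [state for _, state in det.rejections] == [
            DetectorState.S5_PSI]

    def test_two_falls_with_rest_between_give_two_events(self):
        a = generate_fall("fall_forward", seed=1).trace
        b = generate_fall("fall_right", seed=2).trace
        rest_acc = np.zeros((500, 3))
        rest_acc[:, 1] = 1000.0
        acc = np.vstack([a.acc, rest_acc, b.acc])
        gyro = np.vstack([a.gyro, np.zeros((500, 3)), b.gyro])
        trace = ImuTrace.from_arrays(acc, gyro)
        events = detect_stream(trace)
        assert len(events) == 2
        assert detect_offline(trace) == events

    def test_impact_threshold_above_signal_maximum_blocks_detection(
            self, canonical_fall):
        trace = canonical_fall.trace
        too_high = float(trace.asvm().max()) + 1
        cfg = DetectorConfig(impact_thresh=too_high, trigger_thresh=800)
        assert detect_stream(trace, cfg) == []

    def test_truncated_window_discarded(self, canonical_fall):
        trace = canonical_fall.trace
        i0 = int(np.argmax(trace.asvm() < 800))
        cut = ImuTrace(t=trace.t[:i0 + 50], acc=trace.acc[:i0 + 50],
                       gyro=trace.gyro[:i0 + 50])
        det = FallDetector()
        for s in cut:
            det.step(s)
        det.finalize()
        assert det.events == [] and det.truncated
        assert detect_offline(cut) == []

    def test_second_trigger_inside_consumed_window_ignored(self):
        # two dips 50 samples apart; the first window passes all stages, so
        # the second dip lies inside the consumed window -> exactly 1 event
        mag = np.full(600, 1000.0)
        mag[100:110] = 500.0
        mag[150:160] = 500.0   # second sub-trigger dip, 50 samples later
        mag[170:173] = 1800.0  # impact inside the first window
        psi = np.full(600, 90.0)
        psi[220:] = 10.0       # lying by the time the tail slices open
        trace = make_trace(mag, psi)
        events = detect_stream(trace)
        assert len(events) == 1 and events[0].trigger_index == 100
        assert detect_offline(trace) == events

    def test_nonmonotone_timestamps_raise(self):
        det = FallDetector()
        det.step(ImuSample(0.0, 0, 1000, 0, 0, 0, 0))
        with pytest.raises(StreamError):
            det.step(ImuSample(0.0, 0, 1000, 0, 0, 0, 0))

    def test_state_log_has_one_entry_per_sample(self, canonical_fall):
        trace = canonical_fall.trace
        _, log = detect_stream(trace, verbose=True)
        assert len(log) == len(trace)
        assert DetectorState.S6_ALERT in log


class TestShortCircuit:
    """A failed stage aborts without computing later features."""

    def run_detector(self, trace):
        det = FallDetector()
        for s in trace:
            det.step(s)
        det.finalize()
        return det

    def test_sigma_gyro_not_computed_when_sigma_acc_fails(self):
        det = self.run_detector(generate_adl("running", seed=3).trace)
        assert det.events == []
        assert det.stage_evals["sigma_acc"] >= 1
        assert det.stage_evals["sigma_gyro"] == 0
        assert det.stage_evals["psi"] == 0

    def test_sigma_acc_not_computed_when_impact_fails(self):
        det = self.run_detector(generate_adl("upstairs", seed=3).trace)
        assert det.events == []
        assert det.stage_evals["impact"] >= 1
        assert det.stage_evals["sigma_acc"] == 0

    def test_psi_computed_only_after_both_sigmas_pass(self):
        det = self.run_detector(generate_adl("jumping", seed=3).trace)
        assert det.events == []
        assert det.stage_evals["psi"] == det.stage_evals["sigma_gyro"] >= 1


def _random_trace_suite(n, seed):
    """Mixed falls / ADLs / adversarial variants, one small corpus."""
    out = []
    for st in iter_dataset(n_subjects=max(1, n // 19), falls_per_subject=3,
                           adl_per_activity=2, seed=seed,
                           leanback_fraction=0.5,
                           displacement_fraction=0.2):
        out.append(st.trace)
        if len(out) >= n:
            break
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("config", [
        DetectorConfig(),
        DetectorConfig(psi_slice=(181, 400)),
        DetectorConfig(psi_abs=False),
        DetectorConfig(trigger_thresh=900, impact_thresh=1300,
                       sigma_acc_thresh=50),
    ])
    def test_stream_equals_offline(self, config):
        for trace in _random_trace_suite(120, seed=11):
            assert detect_stream(trace, config) == detect_offline(
                trace, config)


class TestThresholdMonotonicity:
    def test_relaxing_thresholds_never_removes_events(self):
        base = DetectorConfig()
        relaxed = [
            DetectorConfig(psi_thresh=90),
            DetectorConfig(sigma_acc_thresh=500, sigma_gyro_thresh=100),
            DetectorConfig(impact_thresh=1000),
        ]
        for trace in _random_trace_suite(60, seed=23):
            got = {e.trigger_index for e in detect_stream(trace, base)}
            for cfg in relaxed:
                wider = {e.trigger_index for e in detect_stream(trace, cfg)}
                assert got <= wider

    def test_raising_trigger_never_removes_the_first_trigger(self):
        lo = DetectorConfig(trigger_thresh=800)
        hi = DetectorConfig(trigger_thresh=950)
        for trace in _random_trace_suite(40, seed=29):
            a = trace.asvm()
            first_lo = np.flatnonzero(a < lo.trigger_thresh)
            first_hi = np.flatnonzero(a < hi.trigger_thresh)
            if first_lo.size:
                assert first_hi.size and first_hi[0] <= first_lo[0]


def test_determinism_bit_for_bit(canonical_fall):
    trace = canonical_fall.trace
    e1 = detect_stream(trace)
    e2 = detect_stream(trace)
    assert e1 == e2  # dataclass equality covers every evidence float
    assert [dataclasses.astuple(a) == dataclasses.astuple(b)
            for a, b in zip(e1, e2)] == [True] * len(e1)
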