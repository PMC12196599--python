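import logging

import numpy as np
import pytest

from fallfsm import DetectorConfig, ImuTrace, generate_fall

# truncation notices from oscillating activities ending mid-window are
# expected; keep test output readable
logging.getLogger("fallfsm.detector").setLevel(logging.ERROR)


@pytest.fixture
def default_config() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def canonical_fall():
    """A left-side fall with fixed seed; trough 450-ish, peak 2000-ish."""
    return generate_fall("fall_left", seed=42)


@pytest.fixture
def quiet_trace() -> ImuTrace:
    """10 s of motionless upright standing: ASVM pinned at 1000 mg."""
    n = 1000
    acc = np.zeros((n, 3))
    acc[:, 1] = 1000.0
    return ImuTrace.from_arrays(acc, np.zeros((n, 3)))


def make_trace(mag: np.ndarray, psi_deg: np.ndarray | float = 90.0,
               gyro: np.ndarray | None = None, fs: float = 100.0) -> ImuTrace:
    """Build a trace from an ASVM envelope and a ψ trajectory."""
    mag = np.asarray(mag, dtype=float)
    n = mag.shape[0]
    psi = np.broadcast_to(np.asarray(psi_deg, dtype=float), (n,))
    r = np.radians(psi)
    acc = np.stack([np.zeros(n), np.sin(r), np.cos(r)], axis=1)
    acc *= mag[:, None]
    if gyro is None:
        gyro = np.zeros((n, 3))
    return ImuTrace.from_arrays(acc, gyro, fs=fs)
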