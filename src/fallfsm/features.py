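"""Signal features for waist-worn six-axis IMU fall detection.

Pure functions mapping raw accelerometer/gyroscope samples (mg, dps) to the
derived quantities the fall-detection state machine consumes:

* ``asvm`` / ``gsvm`` — signal vector magnitudes, the Euclidean norm of a
  tri-axial sample, reducing three axes to one orientation-free channel.
* ``inclination_angles`` — tilt of each body axis against the horizontal
  plane, recovered from the gravity components of the accelerometer.  With
  the device worn upright at the waist the y-axis is vertical, so the
  y-angle ψ sits near +90° when standing and near 0° after a fall.
* ``window_std`` / ``mean_psi`` — windowed statistics over the post-trigger
  evaluation buffer (population-divisor standard deviation and plain mean).

Units are millig (mg) for acceleration, degrees per second (dps) for angular
rate, degrees for angles and Hz for rates throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ACC_FULL_SCALE_MG",
    "GYRO_FULL_SCALE_DPS",
    "ImuSample",
    "ImuTrace",
    "OrientationAngles",
    "WindowFeatures",
    "InvalidSampleError",
    "UndefinedOrientationError",
    "WindowError",
    "asvm",
    "gsvm",
    "inclination_angles",
    "psi_from_components",
    "one_based_slice",
    "window_std",
    "window_mean",
    "mean_psi",
]

#: Configured full-scale ranges of the sensor (±8 g accelerometer,
#: ±500 dps gyroscope).  Samples beyond these are flagged, never clipped.
ACC_FULL_SCALE_MG = 8000.0
GYRO_FULL_SCALE_DPS = 500.0


class InvalidSampleError(ValueError):
    """A sample contained non-finite components."""


class UndefinedOrientationError(ValueError):
    """Inclination angles requested for a zero acceleration vector."""


class WindowError(IndexError):
    """A requested window slice does not fit the series."""


class ImuSample(NamedTuple):
    """One six-axis IMU reading: time (s), acceleration (mg), rate (dps)."""

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float


class OrientationAngles(NamedTuple):
    """Inclination of the x-, y-, z-axis to the horizontal plane, degrees.

    Each angle lies in [-90, +90]; for any non-zero acceleration vector the
    identity sin²θ + sin²ψ + sin²φ = 1 holds.
    """

    theta: float
    psi: float
    phi: float


@dataclass(frozen=True)
class WindowFeatures:
    """Derived statistics of a post-trigger window.

    ``mu_a``/``mu_g`` are the mean ASVM (mg) and GSVM (dps) over the
    standard-deviation slice, ``sigma_acc``/``sigma_gyro`` the matching
    population standard deviations, and ``psi_bar`` the mean y-axis
    inclination (degrees) over the ψ slice.
    """

    mu_a: float
    mu_g: float
    sigma_acc: float
    sigma_gyro: float
    psi_bar: float


@dataclass
class ImuTrace:
    """A fixed-rate sequence of six-axis IMU samples.

    Parameters
    ----------
    t : array of shape (n,)
        Timestamps in seconds, strictly increasing, spaced consistently with
        ``fs`` (within half a sample period by default).
    acc : array of shape (n, 3)
        Tri-axial acceleration in mg.
    gyro : array of shape (n, 3)
        Tri-axial angular rate in dps.
    fs : float
        Sampling frequency in Hz (default 100).
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float = 100.0
    spacing_rtol: float = field(default=0.5, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if n < 1:
            raise ValueError("trace must contain at least one sample")
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"acc/gyro must have shape ({n}, 3); got {self.acc.shape} "
                f"and {self.gyro.shape}"
            )
        if not (np.isfinite(self.t).all() and np.isfinite(self.acc).all()
                and np.isfinite(self.gyro).all()):
            raise InvalidSampleError("trace contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if (dt <= 0).any():
                raise ValueError("timestamps must be strictly increasing")
            period = 1.0 / self.fs
            if (np.abs(dt - period) > self.spacing_rtol * period).any():
                raise ValueError(
                    "sample spacing inconsistent with declared fs"
                )

    # -- construction ----------------------------------------------------

    @classmethod
    def from_samples(cls, samples: Sequence[ImuSample], fs: float = 100.0,
                     **kwargs) -> "ImuTrace":
        arr = np.asarray([tuple(s) for s in samples], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 7:
            raise ValueError("samples must be 7-tuples (t, ax..gz)")
        return cls(t=arr[:, 0], acc=arr[:, 1:4], gyro=arr[:, 4:7], fs=fs,
                   **kwargs)

    @classmethod
    def from_arrays(cls, acc: np.ndarray, gyro: np.ndarray,
                    fs: float = 100.0, t0: float = 0.0) -> "ImuTrace":
        """Build a trace from component arrays at exact ``fs`` spacing."""
        acc = np.asarray(acc, dtype=float)
        n = acc.shape[0]
        t = t0 + np.arange(n) / fs
        return cls(t=t, acc=acc, gyro=np.asarray(gyro, dtype=float), fs=fs)

    # -- basic views -----------------------------------------------------

    def __len__(self) -> int:
        return self.t.shape[0]

    def __iter__(self) -> Iterator[ImuSample]:
        for i in range(len(self)):
            yield ImuSample(self.t[i], *self.acc[i], *self.gyro[i])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def out_of_range_mask(self) -> np.ndarray:
        """Boolean mask of samples exceeding the configured full scales.

        Out-of-range values are flagged, not silently clipped: the caller
        decides whether to reject or keep them.
        """
        acc_bad = (np.abs(self.acc) > ACC_FULL_SCALE_MG).any(axis=1)
        gyr_bad = (np.abs(self.gyro) > GYRO_FULL_SCALE_DPS).any(axis=1)
        return acc_bad | gyr_bad

    # -- derived channels ------------------------------------------------

    def asvm(self) -> np.ndarray:
        """Accelerometer signal vector magnitude per sample (mg)."""
        return np.sqrt((self.acc ** 2).sum(axis=1))

    def gsvm(self) -> np.ndarray:
        """Gyroscope signal vector magnitude per sample (dps)."""
        return np.sqrt((self.gyro ** 2).sum(axis=1))

    def psi(self) -> np.ndarray:
        """Per-sample y-axis inclination ψ (degrees)."""
        return psi_from_components(self.acc[:, 0], self.acc[:, 1],
                                   self.acc[:, 2])


# ---------------------------------------------------------------------------
# scalar / vector feature functions
# ---------------------------------------------------------------------------

def _check_finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise InvalidSampleError(f"non-finite sample component: {v!r}")


def asvm(ax: float, ay: float, az: float) -> float:
    """Accelerometer signal vector magnitude √(ax²+ay²+az²), mg in → mg out."""
    _check_finite(ax, ay, az)
    return math.sqrt(ax * ax + ay * ay + az * az)


def gsvm(gx: float, gy: float, gz: float) -> float:
    """Gyroscope signal vector magnitude √(gx²+gy²+gz²), dps in → dps out."""
    _check_finite(gx, gy, gz)
    return math.sqrt(gx * gx + gy * gy + gz * gz)


def psi_from_components(ax, ay, az):
    """Vectorized y-axis inclination ψ = atan(ay / √(az²+ax²)), degrees.

    A zero horizontal component gives ±90° with the sign of ``ay``
    (``arctan2`` convention).  A fully zero vector maps to 0°; use
    :func:`inclination_angles` when that case must raise.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    return np.degrees(np.arctan2(ay, np.sqrt(az * az + ax * ax)))


def inclination_angles(ax: float, ay: float, az: float) -> OrientationAngles:
    """Inclination of each axis to the horizontal plane from gravity.

    θ = atan(ax/√(ay²+az²)), ψ = atan(ay/√(az²+ax²)), φ = atan(az/√(ax²+ay²)),
    in degrees, each in [-90, +90].  Valid as a tilt estimate only while the
    device is quasi-static (gravity dominates the accelerometer reading).

    Raises
    ------
    UndefinedOrientationError
        If the acceleration vector is exactly zero.
    """
    _check_finite(ax, ay, az)
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise UndefinedOrientationError(
            "inclination undefined for zero acceleration vector"
        )
    theta = np.degrees(np.arctan2(ax, np.hypot(ay, az)))
    psi = np.degrees(np.arctan2(ay, np.hypot(az, ax)))
    phi = np.degrees(np.arctan2(az, np.hypot(ax, ay)))
    return OrientationAngles(float(theta), float(psi), float(phi))


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def one_based_slice(window: tuple[int, int]) -> slice:
    """Convert a 1-based inclusive sample range to a Python slice.

    The detector counts window samples 1…N (sample 1 is the trigger), so the
    default standard-deviation slice (151, 200) maps to ``slice(150, 200)``
    and the ψ slice (181, 200) to ``slice(180, 200)``.  This is the single
    place where the convention is converted.
    """
    start, stop = window
    if start < 1 or stop < start:
        raise WindowError(f"invalid 1-based window {window}")
    return slice(start - 1, stop)


def _window_view(series, window) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    sl = one_based_slice(window)
    if sl.stop > arr.shape[0]:
        raise WindowError(
            f"window {window} out of bounds for series of length {arr.shape[0]}"
        )
    return arr[sl]


def window_mean(series, window: tuple[int, int]) -> float:
    """Mean of ``series`` over a 1-based inclusive sample range."""
    return float(_window_view(series, window).mean())


def window_std(series, window: tuple[int, int]) -> float:
    """Population standard deviation over a 1-based inclusive range.

    Divisor is the slice length (ddof = 0), matching the printed 1/50
    factor of the detector's 50-point stabilisation windows.
    """
    return float(_window_view(series, window).std(ddof=0))


def mean_psi(psi_series, window: tuple[int, int]) -> float:
    """Mean ψ (degrees) over a 1-based inclusive sample range."""
    return window_mean(psi_series, window)
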