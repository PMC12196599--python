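"""Threshold calibration from labelled trial recordings.

The detector's trigger and impact thresholds are set from per-trial
extrema of calibration falls: the ASVM trough during loss of balance and
the ASVM peak at ground impact.  Each set of per-trial values is
approximated by a normal distribution and summarised as mean ± 3·SD next
to the observed extremes; the final rounding of a deployed threshold
(e.g. widening a 653.12 mg trough bound to 800 mg) is a judgment call and
is therefore left to an explicit caller argument — no hidden heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .features import ImuTrace, WindowError, one_based_slice

__all__ = [
    "CalibrationSummary",
    "InsufficientDataError",
    "extract_trough",
    "extract_peak",
    "calibrate",
    "three_sigma_bounds",
]


class InsufficientDataError(ValueError):
    """Fewer than two calibration values were supplied."""


@dataclass(frozen=True)
class CalibrationSummary:
    """Normal-approximation summary of per-trial calibration statistics.

    ``tail`` records which side matters for the threshold: ``"lower"`` for
    trough-like features (threshold above the distribution, mean + 3·SD is
    the relevant bound) and ``"upper"`` for peak-like features (mean − 3·SD).
    ``recommended_threshold`` is whatever the caller chose after rounding;
    it is reported, never derived.
    """

    n: int
    mean: float
    sd: float
    mean_plus_3sd: float
    mean_minus_3sd: float
    observed_min: float
    observed_max: float
    tail: str
    recommended_threshold: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "mean_plus_3sd": self.mean_plus_3sd,
            "mean_minus_3sd": self.mean_minus_3sd,
            "observed_min": self.observed_min,
            "observed_max": self.observed_max,
            "tail": self.tail,
            "recommended_threshold": self.recommended_threshold,
        }


def _window_asvm(trace: ImuTrace, window: tuple[int, int]) -> np.ndarray:
    sl = one_based_slice(window)
    a = trace.asvm()
    if sl.stop > a.shape[0]:
        raise WindowError(
            f"window {window} out of bounds for trace of length {a.shape[0]}"
        )
    return a[sl]


def extract_trough(trace: ImuTrace, window: tuple[int, int]) -> float:
    """Minimum ASVM (mg) over a 1-based inclusive loss-of-balance window."""
    return float(_window_asvm(trace, window).min())


def extract_peak(trace: ImuTrace, window: tuple[int, int]) -> float:
    """Maximum ASVM (mg) over a 1-based inclusive ground-impact window."""
    return float(_window_asvm(trace, window).max())


def three_sigma_bounds(mean: float, sd: float) -> tuple[float, float]:
    """(mean − 3·SD, mean + 3·SD) for an already-known normal fit."""
    return mean - 3.0 * sd, mean + 3.0 * sd


def calibrate(values: Iterable[float] | Sequence[float], tail: str,
              *, ddof: int = 0,
              recommended_threshold: Optional[float] = None
              ) -> CalibrationSummary:
    """Fit a normal approximation to per-trial statistics.

    Parameters
    ----------
    values
        One statistic per calibration trial (trough mg, peak mg, ψ̄ deg, …).
    tail
        ``"lower"`` or ``"upper"`` — which side of the distribution the
        deployed threshold must clear.
    ddof
        SD divisor offset; 0 (population form, the package-wide convention)
        by default, 1 for the sample form.
    recommended_threshold
        The caller's rounded choice, recorded verbatim.

    Invariant to input order.  Raises :class:`InsufficientDataError` for
    fewer than two values.
    """
    if tail not in ("lower", "upper"):
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 calibration values, got {arr.size}"
        )
    if not np.isfinite(arr).all():
        raise ValueError("calibration values must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    lo, hi = three_sigma_bounds(mean, sd)
    return CalibrationSummary(
        n=int(arr.size),
        mean=mean,
        sd=sd,
        mean_plus_3sd=hi,
        mean_minus_3sd=lo,
        observed_min=float(arr.min()),
        observed_max=float(arr.max()),
        tail=tail,
        recommended_threshold=recommended_threshold,
    )
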