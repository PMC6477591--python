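"""MIRD-formalism kidney self-dose from a time-activity curve.

The absorbed dose to a source organ is ``D = A_cum * S``, where ``A_cum``
(cumulated activity, MBq*h) is the time-integral of the organ activity and
``S`` (Gy per MBq*h) is a precomputed dose-conversion factor for the
organ pair.  S-factors are inputs here (typically Monte Carlo values for a
mouse phantom); this module only integrates curves and applies the product.

Units are fixed throughout: activity in MBq, time in hours, dose in Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadionuclideSpec",
    "TimeActivityCurve",
    "DoseResult",
    "LU177",
    "days_to_hours",
    "hours_to_days",
    "decay",
    "effective_lambda",
    "cumulated_activity",
    "absorbed_dose",
]


def days_to_hours(days: float) -> float:
    return days * 24.0


def hours_to_days(hours: float) -> float:
    return hours / 24.0


@dataclass(frozen=True)
class RadionuclideSpec:
    """Physical identity of the radionuclide.

    ``e_max_mev`` (beta endpoint energy) is carried as metadata only; no
    spectrum handling happens here.
    """

    name: str = "Lu-177"
    half_life_days: float = 6.73
    e_max_mev: float = 0.5

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")

    @property
    def half_life_hours(self) -> float:
        return days_to_hours(self.half_life_days)

    @property
    def lambda_phys_per_hour(self) -> float:
        return math.log(2.0) / self.half_life_hours


#: Lutetium-177 (beta emitter used for somatostatin-receptor therapy).
LU177 = RadionuclideSpec()


@dataclass
class TimeActivityCurve:
    """Kidney activity samples over time, with an optional analytic tail.

    ``tail`` is either ``None`` (integrate observed points only, refuse to
    extrapolate) or ``"mono-exponential"``, which appends the closed-form
    integral ``A_last / lambda_eff`` beyond the last sample.
    """

    times_h: np.ndarray
    activities_mbq: np.ndarray
    tail: str | None = None
    lambda_eff_per_h: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_mbq = np.asarray(self.activities_mbq, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.activities_mbq.shape:
            raise ValueError("times and activities must be 1-D and the same length")
        if len(self.times_h) >= 1 and self.times_h[0] < 0:
            raise ValueError("times must be non-negative")
        if len(self.times_h) > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activities_mbq < 0):
            raise ValueError("activities must be non-negative")
        if self.tail not in (None, "mono-exponential"):
            raise ValueError(f"unknown tail model: {self.tail!r}")


@dataclass(frozen=True)
class DoseResult:
    cumulated_activity_mbq_h: float
    s_factor_gy_per_mbq_h: float
    absorbed_dose_gy: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cumulated_activity_mbq_h < 0 or self.s_factor_gy_per_mbq_h < 0:
            raise ValueError("cumulated activity and S-factor must be non-negative")
        object.__setattr__(
            self,
            "absorbed_dose_gy",
            self.cumulated_activity_mbq_h * self.s_factor_gy_per_mbq_h,
        )


def decay(activity_mbq: float, t_h: float, spec: RadionuclideSpec = LU177) -> float:
    """Physical decay: ``A * 2**(-t / t_half)``."""
    if t_h < 0:
        raise ValueError("decay time must be non-negative")
    return activity_mbq * 2.0 ** (-t_h / spec.half_life_hours)


def effective_lambda(lambda_phys_per_h: float, lambda_bio_per_h: float) -> float:
    """Effective clearance rate: physical and biological removal add."""
    if lambda_phys_per_h < 0 or lambda_bio_per_h < 0:
        raise ValueError("decay constants must be non-negative")
    return lambda_phys_per_h + lambda_bio_per_h


def cumulated_activity(curve: TimeActivityCurve) -> float:
    """Integrate a time-activity curve to cumulated activity (MBq*h).

    Trapezoid rule over the observed samples; if the curve declares a
    mono-exponential tail, the analytic remainder ``A_last / lambda_eff``
    is added.  Without a tail model nothing beyond the last sample is
    counted.
    """
    if len(curve.times_h) < 2:
        raise ValueError("need at least two samples for trapezoid integration")
    a_cum = float(np.trapezoid(curve.activities_mbq, curve.times_h))
    if curve.tail == "mono-exponential":
        lam = curve.lambda_eff_per_h
        if lam is None or lam <= 0:
            raise ValueError("mono-exponential tail requires lambda_eff > 0")
        a_cum += float(curve.activities_mbq[-1]) / lam
    return a_cum


def absorbed_dose(a_cum_mbq_h: float, s_factor_gy_per_mbq_h: float) -> DoseResult:
    """Apply the dose-factor product ``D = A_cum * S``."""
    return DoseResult(a_cum_mbq_h, s_factor_gy_per_mbq_h)
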