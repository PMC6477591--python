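"""Survival analysis for the long-term cohorts.

Deaths are classified as radiation-related from a controlled vocabulary of
necropsy findings; animals sacrificed at their scheduled end point, or
removed for humane-endpoint findings only, are censored.  Survival is
estimated with the Kaplan-Meier product-limit estimator and groups are
compared pairwise with the Mantel-Cox log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RADIATION_FINDINGS",
    "HUMANE_FINDINGS",
    "CONTEXTS",
    "VocabularyError",
    "SurvivalRecord",
    "KMCurve",
    "classify_outcome",
    "km_estimate",
    "logrank_test",
]

#: Necropsy findings that classify a death as radiation-related.
RADIATION_FINDINGS = frozenset(
    {
        "swollen liver",
        "swollen kidneys",
        "swollen spleen",
        "pathological spleen",
        "pathological liver",
    }
)

#: Humane-endpoint findings; animals removed for these alone are censored.
HUMANE_FINDINGS = frozenset(
    {
        "weight loss",
        "skin lesions",
        "swollen joints",
        "general physical decline",
    }
)

CONTEXTS = ("died", "terminated_humane_endpoint", "scheduled_sacrifice")


class VocabularyError(ValueError):
    """A necropsy finding outside the controlled vocabulary."""


def classify_outcome(
    findings: set[str] | frozenset[str],
    context: str,
) -> tuple[str, str | None]:
    """Classify an animal's outcome as ``event`` or ``censored``.

    A death counts as a radiation-related event when the animal did not
    reach its scheduled sacrifice AND at least one radiation-related
    finding was present at necropsy.  Everything else is censored, with
    the reason recorded.

    Returns ``(status, censor_reason)`` where ``censor_reason`` is ``None``
    for events.
    """
    if context not in CONTEXTS:
        raise VocabularyError(f"unknown context: {context!r}")
    findings = set(findings)
    unknown = findings - RADIATION_FINDINGS - HUMANE_FINDINGS
    if unknown:
        raise VocabularyError(f"unknown necropsy findings: {sorted(unknown)}")
    if context == "scheduled_sacrifice":
        return "censored", "end of experiment"
    if findings & RADIATION_FINDINGS:
        return "event", None
    return "censored", "humane endpoint without radiation-related findings"


@dataclass
class SurvivalRecord:
    animal_id: str
    arm: str
    time_weeks: int
    status: str  # "event" | "censored"
    findings: frozenset[str] = frozenset()
    context: str = "died"
    censor_reason: str | None = None

    def __post_init__(self) -> None:
        if self.time_weeks < 0:
            raise ValueError("time must be non-negative")
        if self.status not in ("event", "censored"):
            raise ValueError(f"bad status: {self.status!r}")
        self.findings = frozenset(self.findings)


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``times`` holds the distinct event times in increasing order with the
    at-risk count ``n_at_risk``, event count ``n_events`` and the estimate
    ``survival`` immediately after each.  At tied times events are
    processed before censorings (the standard convention).
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time_weeks for r in records], dtype=float)
    events = np.array([r.status == "event" for r in records], dtype=bool)
    if np.any(times < 0):
        raise ValueError("negative time")

    event_times = np.unique(times[events])
    n = len(records)
    out_t, out_n, out_d, out_s = [], [], [], []
    s = 1.0
    for t in event_times:
        # events at t are processed before censorings at t
        at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_n.append(at_risk)
        out_d.append(d)
        out_s.append(s)
    return KMCurve(
        np.array(out_t), np.array(out_n, dtype=int), np.array(out_d, dtype=int), np.array(out_s)
    )


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Cox log-rank test for two groups.

    Sums observed-minus-expected events for group A over the distinct
    event times, with the hypergeometric variance at each time; the
    statistic is chi-square with one degree of freedom.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    t = np.array([r.time_weeks for r in group_a + group_b], dtype=float)
    e = np.array([r.status == "event" for r in group_a + group_b], dtype=bool)
    in_a = np.array([True] * len(group_a) + [False] * len(group_b))
    if not e.any():
        raise ValueError("degenerate test: no events in either group")

    o_minus_e = 0.0
    var = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        n_j = int(at_risk.sum())
        n_aj = int((at_risk & in_a).sum())
        d_j = int((e & (t == tj)).sum())
        d_aj = int((e & (t == tj) & in_a).sum())
        exp_aj = d_j * n_aj / n_j
        o_minus_e += d_aj - exp_aj
        if n_j > 1:
            var += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0.0:
        # all events concentrated where one group is exhausted; no information
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
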