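"""Session performance metrics, index of difficulty, the difficulty-vs-
time regression, and effect sizes (from raw samples or from per-session
summary statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class MetricSet:
    """The five session metrics.

    completion_rate : percent of targets reached.
    completion_time : mean seconds over successful targets (NaN if none).
    path_efficiency : percent, mean over all attempted targets of
        straight-line distance / traversed path length.
    overshoot : boundary-exit events per target.
    throughput : bits/s, mean over successes of ID / completion time
        (NaN if none).
    """

    completion_rate: float
    completion_time: float
    path_efficiency: float
    overshoot: float
    throughput: float

    def as_dict(self) -> dict:
        return {
            "CR": self.completion_rate,
            "CT": self.completion_time,
            "PE": self.path_efficiency,
            "O": self.overshoot,
            "T": self.throughput,
        }


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0 or self.n < 2:
            raise ValueError("summary requires sd >= 0 and n >= 2")


def index_of_difficulty(distance: float, diameter: float) -> float:
    """log2(D / W + 1) bits."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    return math.log2(distance / diameter + 1.0)


def session_metrics(logs) -> MetricSet:
    """Aggregate one session's trial logs into the five metrics."""
    n = len(logs)
    if n == 0:
        raise ValueError("no trials")
    successes = [log for log in logs if log.success]
    cr = 100.0 * len(successes) / n

    ratios = []
    for log in logs:
        path = log.path_length
        ratios.append(log.target.distance / path if path > 0 else 0.0)
    pe = 100.0 * float(np.mean(ratios))

    overshoot = sum(log.overshoots for log in logs) / n

    if successes:
        ct = float(np.mean([log.completion_time for log in successes]))
        tp = float(np.mean([
            index_of_difficulty(log.target.distance, log.target.diameter)
            / log.completion_time
            for log in successes
        ]))
    else:
        ct = float("nan")
        tp = float("nan")
    return MetricSet(cr, ct, pe, overshoot, tp)


def fitts_regression(ids, times) -> tuple[float, float, float]:
    """OLS of completion time on index of difficulty: (slope, intercept, R^2)."""
    ids = np.asarray(ids, float)
    times = np.asarray(times, float)
    if np.unique(ids).size < 2:
        raise ValueError("degenerate regression: constant index of difficulty")
    if np.allclose(times, times[0]):
        raise ValueError("degenerate regression: constant completion time")
    res = sps.linregress(ids, times)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _as_summary(group) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    arr = np.asarray(group, float)
    # population SD: keeps the equal-n pooled form an exact identity on
    # raw samples (summaries built from printed tables carry their own SD)
    return GroupSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=0)), n=arr.size)


def cohens_d(a, b) -> float:
    """Effect size (mean_a - mean_b) / pooled SD, equal-n pooled form
    s_p = sqrt((s_a^2 + s_b^2) / 2).  Accepts sample arrays or
    :class:`GroupSummary` objects."""
    sa, sb = _as_summary(a), _as_summary(b)
    pooled = math.sqrt((sa.sd ** 2 + sb.sd ** 2) / 2.0)
    if pooled == 0:
        raise ZeroDivisionError("zero pooled variance")
    return (sa.mean - sb.mean) / pooled


def concatenate_sessions(*sessions: GroupSummary) -> GroupSummary:
    """Moments of the pooled group from equal-n per-session summaries:
    mean of means; variance = mean of variances + variance of means."""
    ns = {s.n for s in sessions}
    if len(ns) != 1:
        raise ValueError("sessions must have equal n")
    means = np.array([s.mean for s in sessions])
    variances = np.array([s.sd ** 2 for s in sessions])
    mean = float(means.mean())
    var = float(variances.mean() + ((means - mean) ** 2).mean())
    return GroupSummary(mean=mean, sd=math.sqrt(var), n=len(sessions) * sessions[0].n)


def cross_session_mean(day_a: GroupSummary, day_b: GroupSummary) -> float:
    """Arithmetic mean of two equal-n session means."""
    if day_a.n != day_b.n:
        raise ValueError("sessions must have equal n")
    return (day_a.mean + day_b.mean) / 2.0
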