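"""Order-i inter-FP intervals and probability-of-observation curves.

For a train of FP occurrence times t(1) < ... < t(N), the order-i interval is
I_i(n) = t(n+i) - t(n) for n = 1..N-i: the time needed for i further FPs to
occur after the n-th. Pooling I_i over all valid n (and all muscles) and
taking the empirical cumulative distribution gives, for each observation
duration T, the probability that i FPs will have been observed within T —
the quantity that answers "how long must one record before concluding FPs
are absent?". The censored interval from the last FP to the end of the
recording is excluded (the formula spans n <= N-i only), which biases the
extreme tail slightly downward.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import EventTrain

__all__ = [
    "IntervalSet",
    "CumulativeCurve",
    "TrainSummary",
    "compute_intervals",
    "pool_and_cumulate",
    "duration_for_probability",
    "summarize_train",
]

POOL_ALL = "all_intervals"
POOL_MAX = "per_muscle_max"


@dataclass(eq=False)
class IntervalSet:
    """The order-i intervals of one muscle's train."""

    order: int
    intervals_s: np.ndarray          # length max(N - i, 0), all > 0
    muscle_id: str = ""

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        if self.intervals_s.size and np.any(self.intervals_s <= 0):
            raise ValueError("intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.intervals_s.size)


@dataclass(eq=False)
class CumulativeCurve:
    """Pooled empirical probability of observing i FPs within a duration T.

    ``probabilities[k]`` is the fraction of pooled order-i intervals that are
    <= ``durations_s[k]`` (right-continuous), so the curve is non-decreasing
    and reaches 1 at the maximum pooled interval.
    """

    order: int
    durations_s: np.ndarray
    probabilities: np.ndarray
    n_intervals: int
    pooling: str = POOL_ALL
    grid_step_s: float = 1.0

    def __post_init__(self) -> None:
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.durations_s.shape != self.probabilities.shape:
            raise ValueError("durations and probabilities must align")
        if self.n_intervals <= 0:
            raise ValueError("n_intervals must be positive")
        if np.any(np.diff(self.probabilities) < 0):
            raise ValueError("probabilities must be non-decreasing")
        if self.probabilities.size and self.probabilities[-1] != 1.0:
            raise ValueError("curve must reach probability 1")

    def probability_at(self, duration_s: float) -> float:
        """Curve value at an arbitrary duration (step interpolation)."""
        idx = np.searchsorted(self.durations_s, duration_s, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.probabilities[min(idx, self.probabilities.size - 1)])


@dataclass(eq=False)
class TrainSummary:
    """Per-muscle summary: count, rate, interval skewness and order maxima."""

    muscle_id: str
    n_events: int
    rate_per_min: float
    skewness: float                             # NaN when N < 4
    max_interval_per_order_s: dict[int, float]  # order -> max I_i (NaN if N <= i)


def compute_intervals(train: EventTrain, order: int) -> IntervalSet:
    """I_i(n) = t(n+i) - t(n) for n = 1..N-i; empty when N <= i."""
    if order < 1:
        raise ValueError("order must be >= 1")
    t = train.times
    if t.size <= order:
        ivals = np.empty(0)
    else:
        ivals = t[order:] - t[:-order]
    return IntervalSet(order=order, intervals_s=ivals, muscle_id=train.muscle_id)


def pool_and_cumulate(interval_sets: Sequence[IntervalSet],
                      order: int | None = None,
                      grid_step_s: float = 1.0,
                      pooling: str = POOL_ALL) -> CumulativeCurve:
    """Pool interval sets of one order and build the cumulative curve.

    With ``pooling="all_intervals"`` every interval from every muscle enters
    with equal weight; with ``"per_muscle_max"`` only each muscle's longest
    order-i interval is pooled (a conservative, worst-case variant). The
    duration grid spans [0, max pooled interval] in steps of ``grid_step_s``.
    """
    if pooling not in (POOL_ALL, POOL_MAX):
        raise ValueError(f"unknown pooling {pooling!r}")
    if grid_step_s <= 0:
        raise ValueError("grid_step_s must be positive")
    if not interval_sets:
        raise ValueError("need at least one interval set")
    orders = {s.order for s in interval_sets}
    if len(orders) > 1:
        raise ValueError(f"mixed interval orders {sorted(orders)}")
    ord_i = orders.pop()
    if order is not None and order != ord_i:
        raise ValueError(f"interval sets have order {ord_i}, expected {order}")
    if pooling == POOL_ALL:
        parts = [s.intervals_s for s in interval_sets if s.n]
        pooled = np.concatenate(parts) if parts else np.empty(0)
    else:
        pooled = np.array([float(s.intervals_s.max())
                           for s in interval_sets if s.n])
    if pooled.size == 0:
        raise ValueError(f"no intervals at order {ord_i}")
    pooled.sort()
    n_steps = int(math.ceil(pooled[-1] / grid_step_s - 1e-12))
    grid = np.arange(n_steps + 1) * grid_step_s
    if grid[-1] < pooled[-1]:
        grid = np.append(grid, grid[-1] + grid_step_s)
    probs = np.searchsorted(pooled, grid, side="right") / pooled.size
    return CumulativeCurve(order=ord_i, durations_s=grid, probabilities=probs,
                           n_intervals=int(pooled.size), pooling=pooling,
                           grid_step_s=grid_step_s)


def duration_for_probability(curve: CumulativeCurve, p: float) -> float:
    """Smallest grid duration at which the curve reaches probability p.

    For p = 1 this equals the maximum pooled interval, up to one grid step.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    idx = int(np.argmax(curve.probabilities >= p))
    return float(curve.durations_s[idx])


def summarize_train(train: EventTrain, max_order: int = 5) -> TrainSummary:
    """Rate, interval skewness and per-order interval maxima for one train.

    Skewness is the Fisher–Pearson adjusted sample skewness of the order-1
    intervals, defined for N >= 4 events (NaN below that, and 0 for exactly
    equally spaced events, whose interval spread is zero).
    """
    i1 = compute_intervals(train, 1).intervals_s
    if train.n < 4:
        skew = float("nan")
    elif np.ptp(i1) == 0.0:
        skew = 0.0
    else:
        skew = float(stats.skew(i1, bias=False))
    maxima = {}
    for i in range(1, max_order + 1):
        s = compute_intervals(train, i)
        maxima[i] = float(s.intervals_s.max()) if s.n else float("nan")
    return TrainSummary(muscle_id=train.muscle_id, n_events=train.n,
                        rate_per_min=train.rate_per_min, skewness=skew,
                        max_interval_per_order_s=maxima)
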