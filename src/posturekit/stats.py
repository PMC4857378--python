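"""Aggregation of a posture metric across repeated frames.

Filming a rotating subject yields many frames in nearly the same
position; averaging the per-frame measurements suppresses parallax and
annotation error.  This module provides the statistics used to validate
such an instrument against an object of known dimensions:

* summary statistics of the series (mean, sample SD, CV%, extremes);
* the *accumulated* series — for each frame count k, the running mean
  over the first k values, the sample SD of the running means
  themselves, and the resulting accumulated CV%;
* the repetitions-needed (stabilization) analysis: the smallest k after
  which the accumulated CV no longer changes, which tells the operator
  how many frames must be averaged before the instrument's output can
  be trusted.

Accumulated SD semantics
------------------------
The accumulated SD at frame count k is defined here as the **sample
standard deviation of the running means** X̄(1), …, X̄(k) (denominator
k − 1; zero at k = 1), not the SD of the raw values.  This is the only
definition consistent with the reference validation table this package
reproduces, and it measures exactly the quantity of interest for
stabilization: how much the *averaged* estimate is still moving.

Rounding policies
-----------------
Published validation tables typically print means and SDs rounded to
two decimals and form CV = 100·SD/mean from the printed values.  The
default ``"printed-table"`` policy reproduces that convention (half-up
rounding of SD and mean to ``cv_decimals`` places before the ratio);
the ``"exact"`` policy uses full-precision values and is the right
choice for downstream scientific use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, UndefinedReferenceError

__all__ = [
    "RoundingPolicy",
    "PRINTED_TABLE",
    "EXACT",
    "MetricSeries",
    "SummaryStats",
    "AccumulatedStatsRow",
    "StabilizationResult",
    "round_half_up",
    "summary_stats",
    "accumulated_stats",
    "repetitions_needed",
    "percent_error",
    "aggregate_metrics",
    "MetricAggregate",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 decimals).

    Python's built-in ``round`` is banker's rounding, which does not
    match how printed tables round; half-up does.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RoundingPolicy:
    """How CV% is formed from mean and SD.

    ``pre_round``: round SD and mean half-up to ``cv_decimals`` places
    before taking 100·SD/mean (reproduces printed tables); otherwise the
    full-precision ratio is used.
    """

    name: str
    pre_round: bool
    cv_decimals: int = 2

    def cv(self, sd: float, mean: float) -> float:
        if self.pre_round:
            sd = round_half_up(sd, self.cv_decimals)
            mean = round_half_up(mean, self.cv_decimals)
        if mean == 0:
            return 0.0 if sd == 0 else float("inf")
        return 100.0 * sd / mean


PRINTED_TABLE = RoundingPolicy("printed-table", pre_round=True)
EXACT = RoundingPolicy("exact", pre_round=False)

_POLICIES = {"printed-table": PRINTED_TABLE, "exact": EXACT}


def _policy(rounding: "RoundingPolicy | str | None") -> RoundingPolicy:
    if rounding is None:
        return PRINTED_TABLE
    if isinstance(rounding, RoundingPolicy):
        return rounding
    try:
        return _POLICIES[rounding]
    except KeyError:
        raise ValueError(
            f"unknown rounding policy {rounding!r}; expected one of {sorted(_POLICIES)}"
        ) from None


@dataclass(frozen=True)
class MetricSeries:
    """Ordered per-frame measurements of one metric."""

    metric_name: str
    values: tuple[float, ...]
    frame_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        if not values:
            raise InsufficientDataError(f"metric {self.metric_name!r} has no values")
        idx = tuple(int(i) for i in self.frame_indices) or tuple(range(len(values)))
        if len(idx) != len(values):
            raise ValueError("frame_indices and values must have equal length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_indices", idx)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD, CV% (per rounding policy), min and max."""

    n: int
    mean: float
    sd: float
    cv: float
    min: float
    max: float


@dataclass(frozen=True)
class AccumulatedStatsRow:
    """Running statistics after the first k frames."""

    k: int
    mean_accum: float
    sd_accum: float
    cv_accum: float


@dataclass(frozen=True)
class StabilizationResult:
    """Outcome of the repetitions-needed analysis for one metric."""

    k_stable: Optional[int]
    stabilized: bool
    criterion: str
    cv_series: tuple[float, ...]
    metric_name: str = ""


def _as_series(series) -> MetricSeries:
    if isinstance(series, MetricSeries):
        return series
    return MetricSeries("series", tuple(series))


def summary_stats(series, rounding: RoundingPolicy | str | None = None) -> SummaryStats:
    """Mean, sample SD (denominator n−1), CV%, min and max of a series.

    Mean and SD are returned at full precision; only the CV is subject
    to the rounding policy (see module docstring).
    """
    s = _as_series(series)
    policy = _policy(rounding)
    v = np.asarray(s.values, dtype=float)
    if len(v) < 2:
        raise InsufficientDataError(
            f"summary statistics need >= 2 values, got {len(v)} for {s.metric_name!r}"
        )
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return SummaryStats(
        n=len(v), mean=mean, sd=sd, cv=policy.cv(sd, mean),
        min=float(v.min()), max=float(v.max()),
    )


def accumulated_stats(
    series, rounding: RoundingPolicy | str | None = None
) -> list[AccumulatedStatsRow]:
    """Accumulated mean / SD / CV% for every frame count k = 1..n.

    Running means are carried at full precision; the accumulated SD at
    k is the sample SD of the first k running means (0 at k = 1); the
    accumulated CV follows the rounding policy.
    """
    s = _as_series(series)
    policy = _policy(rounding)
    v = np.asarray(s.values, dtype=float)
    means = np.cumsum(v) / np.arange(1, len(v) + 1)
    rows = []
    for k in range(1, len(v) + 1):
        sd_k = float(np.std(means[:k], ddof=1)) if k > 1 else 0.0
        rows.append(
            AccumulatedStatsRow(
                k=k,
                mean_accum=float(means[k - 1]),
                sd_accum=sd_k,
                cv_accum=policy.cv(sd_k, float(means[k - 1])),
            )
        )
    return rows


def repetitions_needed(
    rows: Sequence[AccumulatedStatsRow],
    rule: str = "terminal-plateau",
    *,
    decimals: int = 2,
    epsilon: float = 0.05,
    window: int = 5,
    metric_name: str = "",
) -> StabilizationResult:
    """Smallest frame count at which the accumulated CV has stabilized.

    Rules
    -----
    ``"terminal-plateau"`` (default)
        k_stable is the smallest k >= 2 such that the CV rounded
        half-up to ``decimals`` places is identical for every frame
        count from k through the last row: once the instrument reaches
        its final CV it never leaves it.
    ``"delta-threshold"``
        k_stable is the smallest k such that max − min of the CV over
        rows k .. k+window does not exceed ``epsilon`` (CV percentage
        points).

    A series that never satisfies the rule yields a not-stabilized
    result (flag, not an exception).
    """
    if len(rows) < 2:
        raise InsufficientDataError("stabilization analysis needs >= 2 accumulated rows")
    cv = [row.cv_accum for row in rows]
    if rule == "terminal-plateau":
        rounded = [round_half_up(c, decimals) for c in cv]
        criterion = f"terminal-plateau(decimals={decimals})"
        k_stable = None
        final = rounded[-1]
        for k in range(2, len(rounded) + 1):
            if all(r == final for r in rounded[k - 1 :]):
                k_stable = k
                break
        cv_used = tuple(rounded)
    elif rule == "delta-threshold":
        criterion = f"delta-threshold(epsilon={epsilon}, window={window})"
        k_stable = None
        # the full window [k, k+w] must exist for the rule to fire
        for k in range(2, len(cv) - window + 1):
            seg = cv[k - 1 : k - 1 + window + 1]
            if max(seg) - min(seg) <= epsilon:
                k_stable = k
                break
        cv_used = tuple(cv)
    else:
        raise ValueError(f"unknown stabilization rule {rule!r}")
    return StabilizationResult(
        k_stable=k_stable,
        stabilized=k_stable is not None,
        criterion=criterion,
        cv_series=cv_used,
        metric_name=metric_name,
    )


def percent_error(measured: float, truth: float) -> float:
    """Absolute percent error of a measurement against a known truth."""
    if truth == 0:
        raise UndefinedReferenceError("percent error is undefined for a zero reference")
    return 100.0 * abs(measured - truth) / abs(truth)


@dataclass(frozen=True)
class MetricAggregate:
    """Per-metric aggregation output across frames."""

    summary: SummaryStats
    accumulated: tuple[AccumulatedStatsRow, ...]
    n_skipped: int


def aggregate_metrics(
    per_frame: Sequence[Mapping[str, float]],
    rounding: RoundingPolicy | str | None = None,
) -> dict[str, MetricAggregate | None]:
    """Summary + accumulated statistics for every metric across frames.

    ``per_frame`` is one mapping metric→value per frame (e.g. the
    ``values`` of :class:`posturekit.metrics.MeasuredFrame`).  Frames
    missing a metric are skipped for that metric and counted in
    ``n_skipped``.  A metric observed in fewer than 2 frames maps to
    None (insufficient data flag).
    """
    if len(per_frame) < 2:
        raise InsufficientDataError("aggregation needs >= 2 frames")
    names: list[str] = []
    for frame in per_frame:
        for name in frame:
            if name not in names:
                names.append(name)
    out: dict[str, MetricAggregate | None] = {}
    for name in names:
        values = [f[name] for f in per_frame if name in f]
        skipped = len(per_frame) - len(values)
        if len(values) < 2:
            out[name] = None
            continue
        series = MetricSeries(name, tuple(values))
        out[name] = MetricAggregate(
            summary=summary_stats(series, rounding),
            accumulated=tuple(accumulated_stats(series, rounding)),
            n_skipped=skipped,
        )
    return out
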