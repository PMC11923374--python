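"""Eating-architecture variables: size, timing and frequency of EOs.

Seven variables are derived per participant-day and averaged (unweighted)
over recorded days:

================  =====================================================
frequency         number of EOs in the day (EOs/day)
size_g            mean grams per EO that day
size_kcal         mean kilocalories per EO that day
first_min         clock time of the first EO (minutes since midnight)
last_min          clock time of the last EO
window_min        eating window: last_min - first_min
interval_min      intermeal interval: mean gap between consecutive EOs,
                  undefined (NaN) on single-EO days
================  =====================================================

Because consecutive gaps telescope, a day's mean gap equals
``window_min / (frequency - 1)`` whenever ``frequency >= 2``; single-EO days
have a zero window and contribute nothing to the interval average.  Clock
times are averaged arithmetically on the minute scale (all valid times fall
within one day, so no circular statistics are needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .occasion_builder import BROAD, PRECISE, EatingOccasion
from .slot_coding import format_clock, format_duration

#: Canonical variable order used across tables and agreement analyses.
VARIABLES = (
    "size_g",
    "size_kcal",
    "first_min",
    "last_min",
    "window_min",
    "interval_min",
    "frequency",
)

#: Variables rendered as 24-h clock times vs durations in reports.
CLOCK_VARIABLES = ("first_min", "last_min")
DURATION_VARIABLES = ("window_min", "interval_min")


@dataclass(frozen=True)
class DayArchitecture:
    participant_id: str
    day_index: int
    method: str
    frequency: int
    size_g: float
    size_kcal: float
    first_min: float
    last_min: float
    window_min: float
    interval_min: float  # NaN when frequency == 1


@dataclass(frozen=True)
class ParticipantArchitecture:
    """Per-participant means of the daily variables under one method.

    ``interval_min`` is averaged over the days where it is defined and is
    NaN only if no day had two or more EOs.
    """

    participant_id: str
    method: str
    n_days: int
    frequency: float
    size_g: float
    size_kcal: float
    first_min: float
    last_min: float
    window_min: float
    interval_min: float

    def get(self, variable: str) -> float:
        return getattr(self, variable)


def day_architecture(eos: Sequence[EatingOccasion]) -> DayArchitecture:
    """Compute the daily variables from one day's time-sorted EO list."""
    if not eos:
        raise ValueError("empty EO list")
    times = [eo.time_min for eo in eos]
    if times != sorted(times):
        raise ValueError("EO list must be sorted by time")
    n = len(eos)
    window = float(times[-1] - times[0])
    return DayArchitecture(
        participant_id=eos[0].participant_id,
        day_index=eos[0].day_index,
        method=eos[0].method,
        frequency=n,
        size_g=sum(eo.grams for eo in eos) / n,
        size_kcal=sum(eo.kcal for eo in eos) / n,
        first_min=float(times[0]),
        last_min=float(times[-1]),
        window_min=window,
        interval_min=window / (n - 1) if n >= 2 else math.nan,
    )


def participant_architecture(
    days: Sequence[DayArchitecture], method: str | None = None
) -> ParticipantArchitecture:
    """Unweighted mean of each daily variable over recorded days."""
    if not days:
        raise ValueError("no days to average")
    methods = {d.method for d in days}
    pids = {d.participant_id for d in days}
    if len(methods) > 1 or len(pids) > 1:
        raise ValueError("days span multiple participants or methods")
    if method is not None and days[0].method != method:
        raise ValueError(f"days carry method {days[0].method!r}, expected {method!r}")

    def mean(values: list[float]) -> float:
        return sum(values) / len(values)

    intervals = [d.interval_min for d in days if not math.isnan(d.interval_min)]
    return ParticipantArchitecture(
        participant_id=days[0].participant_id,
        method=days[0].method,
        n_days=len(days),
        frequency=mean([float(d.frequency) for d in days]),
        size_g=mean([d.size_g for d in days]),
        size_kcal=mean([d.size_kcal for d in days]),
        first_min=mean([d.first_min for d in days]),
        last_min=mean([d.last_min for d in days]),
        window_min=mean([d.window_min for d in days]),
        interval_min=mean(intervals) if intervals else math.nan,
    )


def cohort_architecture(
    occasions_by_method: dict[str, dict[str, dict[int, list[EatingOccasion]]]],
) -> list[ParticipantArchitecture]:
    """Per-participant architecture for both methods from built cohort EOs."""
    out = []
    for method in (PRECISE, BROAD):
        for pid in sorted(occasions_by_method[method]):
            per_day = occasions_by_method[method][pid]
            days = [day_architecture(per_day[d]) for d in sorted(per_day)]
            out.append(participant_architecture(days))
    return out


def architecture_frame(
    participants: Iterable[ParticipantArchitecture],
) -> pd.DataFrame:
    """Tidy table: one row per participant x method, one column per variable."""
    rows = [
        {
            "participant_id": p.participant_id,
            "method": p.method,
            "n_days": p.n_days,
            **{v: p.get(v) for v in VARIABLES},
        }
        for p in participants
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "method", "n_days", *VARIABLES]
    )


def cohort_summary(participants: Sequence[ParticipantArchitecture]) -> pd.DataFrame:
    """Mean (SD) of each variable over participants, both methods side by side.

    SD uses the n-1 denominator (NaN for a single participant); interval means
    are over participants with a defined interval, with per-cell n reported.
    """
    if not participants:
        raise ValueError("empty cohort")
    frame = architecture_frame(participants)
    rows = []
    for variable in VARIABLES:
        for method in (PRECISE, BROAD):
            vals = frame.loc[frame["method"] == method, variable].dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "variable": variable,
                    "method": method,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "method", "n", "mean", "sd"])


def _format_mean(variable: str, minutes: float) -> str:
    if variable in CLOCK_VARIABLES:
        return format_clock(minutes)
    if variable in DURATION_VARIABLES:
        return format_duration(minutes)
    return f"{minutes:.1f}"


def _format_sd(variable: str, minutes: float) -> str:
    # the spread of a clock time is itself a duration
    if variable in CLOCK_VARIABLES + DURATION_VARIABLES:
        return format_duration(minutes)
    return f"{minutes:.1f}"


def summary_report(summary: pd.DataFrame) -> str:
    """Aligned-text rendering of :func:`cohort_summary` with clock/duration units."""
    lines = [f"{'variable':<14}{'method':<10}{'n':>6}  {'mean':>12}  {'sd':>12}"]
    for _, row in summary.iterrows():
        lines.append(
            f"{row['variable']:<14}{row['method']:<10}{row['n']:>6}  "
            f"{_format_mean(row['variable'], row['mean']):>12}  "
            f"{_format_sd(row['variable'], row['sd']):>12}"
        )
    return "\n".join(lines)


def intercorrelation_matrix(
    participants: Sequence[ParticipantArchitecture], method: str
) -> pd.DataFrame:
    """Pearson correlation matrix of the seven variables within one method."""
    frame = architecture_frame(
        [p for p in participants if p.method == method]
    )[list(VARIABLES)]
    if frame.empty:
        raise ValueError(f"no participants for method {method!r}")
    return frame.corr(method="pearson")
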