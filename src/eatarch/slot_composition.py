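"""Within-slot composition: how many precise EOs a broad EO absorbs, and
how far apart they are.

When a meal slot contains several distinct precise eating times, broad
coding merges them into one EO.  This module quantifies that merging per
slot: the distribution of member counts, the consecutive time gaps between
merged precise EOs (with the share at or beyond the conventional 15-min and
at or below the 60-min EO-separation cutoffs), per-slot EO size by method,
and the per-participant frequency of precise EOs per occupied slot.

Gaps are *consecutive* sorted differences, not all-pairs distances, matching
the usual definition of an intermeal interval.  Percentiles use the
inclusive linear-interpolation convention (numpy's default "linear").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .occasion_builder import BROAD, PRECISE, EatingOccasion
from .slot_coding import DEFAULT_SCHEME, MealSlot, SlotScheme


@dataclass
class SlotComposition:
    """Merging structure of one meal slot across a cohort's broad EOs."""

    slot: MealSlot
    eo_counts: dict[int, int]  # n_precise_members -> number of broad EOs
    gaps_min: list[float]  # all consecutive within-EO gaps
    mean_gaps: list[float]  # one mean gap per multi-member broad EO

    @property
    def n_broad(self) -> int:
        return sum(self.eo_counts.values())

    @property
    def n_multi(self) -> int:
        return sum(c for k, c in self.eo_counts.items() if k >= 2)

    def gap_summary(self) -> dict:
        """Median, IQR, and 10th/90th percentiles of per-EO mean gaps."""
        if not self.mean_gaps:
            return {
                "slot": self.slot.name,
                "n_multi": 0,
                "median": np.nan,
                "q1": np.nan,
                "q3": np.nan,
                "p10": np.nan,
                "p90": np.nan,
            }
        arr = np.asarray(self.mean_gaps)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        p10, p90 = np.percentile(arr, [10, 90])
        return {
            "slot": self.slot.name,
            "n_multi": self.n_multi,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "p10": float(p10),
            "p90": float(p90),
        }


def within_slot_gaps(
    broad_eos: Iterable[EatingOccasion], scheme: SlotScheme = DEFAULT_SCHEME
) -> dict[str, SlotComposition]:
    """Per-slot composition from broad EOs carrying their member precise times.

    For every broad EO with two or more members, the consecutive sorted gaps
    and their mean are recorded under the EO's slot.  Slots never occupied by
    a multi-member EO still appear, with empty gap lists.
    """
    comps = {
        s.name: SlotComposition(slot=s, eo_counts={}, gaps_min=[], mean_gaps=[])
        for s in scheme
    }
    for eo in broad_eos:
        if eo.method != BROAD:
            raise ValueError("within_slot_gaps expects broad EOs")
        comp = comps[eo.slot.name]
        k = eo.n_precise_members
        comp.eo_counts[k] = comp.eo_counts.get(k, 0) + 1
        if k >= 2:
            times = sorted(eo.member_times)
            gaps = [float(b - a) for a, b in zip(times, times[1:])]
            comp.gaps_min.extend(gaps)
            comp.mean_gaps.append(sum(gaps) / len(gaps))
    return comps


def cutoff_fractions(
    compositions: dict[str, SlotComposition],
    cutoffs: Sequence[float] = (15.0, 60.0),
) -> pd.DataFrame:
    """Per-slot share of within-slot gaps at each separation cutoff.

    For each cutoff c the table reports both the fraction of gaps >= c and
    the fraction <= c, both inclusive: ties at 15 min count as "separated by
    at least 15 min" and ties at 60 min count as "60 min or less".
    """
    rows = []
    for name, comp in compositions.items():
        gaps = np.asarray(comp.gaps_min, dtype=float)
        row: dict = {"slot": name, "n_gaps": int(len(gaps))}
        for c in cutoffs:
            key = f"{c:g}"
            if len(gaps) == 0:
                row[f"frac_ge_{key}"] = np.nan
                row[f"frac_le_{key}"] = np.nan
            else:
                row[f"frac_ge_{key}"] = float(np.count_nonzero(gaps >= c) / len(gaps))
                row[f"frac_le_{key}"] = float(np.count_nonzero(gaps <= c) / len(gaps))
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_gaps(compositions: dict[str, SlotComposition]) -> np.ndarray:
    """All within-slot gaps pooled across slots (for cohort-level summaries)."""
    return np.concatenate(
        [np.asarray(c.gaps_min, dtype=float) for c in compositions.values()]
        or [np.empty(0)]
    )


def slot_size_summary(
    precise_eos: Iterable[EatingOccasion],
    broad_eos: Iterable[EatingOccasion],
    scheme: SlotScheme = DEFAULT_SCHEME,
    z: float = 1.96,
) -> pd.DataFrame:
    """Mean EO grams per slot and method with normal-approximation 95% CIs.

    Slots with no EO under a method are absent from the output; a slot with a
    single EO has an undefined (NaN) CI.
    """
    rows = []
    for method, eos in ((PRECISE, precise_eos), (BROAD, broad_eos)):
        by_slot: dict[str, list[float]] = {}
        for eo in eos:
            if eo.method != method:
                raise ValueError(f"expected {method} EOs")
            by_slot.setdefault(eo.slot.name, []).append(eo.grams)
        for name in sorted(by_slot, key=scheme.slot_order):
            vals = np.asarray(by_slot[name])
            mean = float(vals.mean())
            if len(vals) >= 2:
                se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
                lo, hi = mean - z * se, mean + z * se
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "slot": name,
                    "method": method,
                    "n_eos": int(len(vals)),
                    "mean_g": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(
        rows, columns=["slot", "method", "n_eos", "mean_g", "ci_low", "ci_high"]
    )


def slot_frequency_summary(
    precise_by_participant: dict[str, dict[int, list[EatingOccasion]]],
    scheme: SlotScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Median (IQR) across participants of precise EOs per occupied slot.

    For each participant and slot, the mean number of precise EOs falling in
    that slot over the days on which the slot is occupied (days where the
    slot holds no EO do not dilute the mean).  The broad counterpart of this
    quantity is identically 1.
    """
    per_participant: dict[str, list[float]] = {s.name: [] for s in scheme}
    for pid, per_day in precise_by_participant.items():
        counts: dict[str, list[int]] = {}
        for day, eos in per_day.items():
            day_counts: dict[str, int] = {}
            for eo in eos:
                if eo.method != PRECISE:
                    raise ValueError("expected precise EOs")
                day_counts[eo.slot.name] = day_counts.get(eo.slot.name, 0) + 1
            for name, c in day_counts.items():
                counts.setdefault(name, []).append(c)
        for name, day_vals in counts.items():
            per_participant[name].append(sum(day_vals) / len(day_vals))
    rows = []
    for s in scheme:
        vals = np.asarray(per_participant[s.name], dtype=float)
        if len(vals) == 0:
            rows.append(
                {
                    "slot": s.name,
                    "n_participants": 0,
                    "median": np.nan,
                    "q1": np.nan,
                    "q3": np.nan,
                }
            )
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "slot": s.name,
                "n_participants": int(len(vals)),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
            }
        )
    return pd.DataFrame(rows, columns=["slot", "n_participants", "median", "q1", "q3"])


def gap_summary_frame(compositions: dict[str, SlotComposition]) -> pd.DataFrame:
    """One row per slot: distribution summary of per-EO mean gaps."""
    return pd.DataFrame([c.gap_summary() for c in compositions.values()])


def composition_long_frame(compositions: dict[str, SlotComposition]) -> pd.DataFrame:
    """Long-format export of every within-slot gap for external plotting."""
    rows = [
        {"slot": name, "gap_min": g}
        for name, comp in compositions.items()
        for g in comp.gaps_min
    ]
    return pd.DataFrame(rows, columns=["slot", "gap_min"])
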