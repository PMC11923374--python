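"""Construct eating occasions (EOs) from food records, precisely and broadly.

Under the **precise** definition an EO is all records of one participant-day
sharing one exact clock time; under the **broad** definition an EO is all
records falling in one occupied meal slot, timed at the slot's representative
clock time.  Broad construction therefore *coarsens* precise construction:
every broad EO absorbs one or more whole precise EOs, and grams/kilocalories
are conserved exactly under both groupings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .diary_core import Diary, FoodRecord
from .slot_coding import DEFAULT_SCHEME, MealSlot, SlotScheme

PRECISE = "precise"
BROAD = "broad"


@dataclass(frozen=True)
class EatingOccasion:
    """A grouped eating event under one timing definition.

    ``member_times`` holds the distinct precise clock times merged into this
    EO (a single time for precise EOs), so within-slot composition can be
    analysed without re-deriving the grouping.
    """

    participant_id: str
    day_index: int
    method: str  # PRECISE or BROAD
    time_min: int
    slot: MealSlot
    grams: float
    kcal: float
    n_records: int
    member_times: tuple[int, ...]

    @property
    def n_precise_members(self) -> int:
        return len(self.member_times)


def _check_day(records: Sequence[FoodRecord]) -> None:
    if not records:
        raise ValueError("empty participant-day: no records to group")
    if any(not r.time_valid for r in records):
        raise ValueError("records with missing/invalid times reached EO construction")
    pids = {r.participant_id for r in records}
    days = {r.day_index for r in records}
    if len(pids) > 1 or len(days) > 1:
        raise ValueError("records span more than one participant-day")


def build_precise_occasions(
    records: Sequence[FoodRecord], scheme: SlotScheme = DEFAULT_SCHEME
) -> list[EatingOccasion]:
    """One EO per distinct clock time of one participant-day, time-sorted.

    Identity is exact minute equality — no merge tolerance; records sharing
    a time have grams and kcal summed.
    """
    _check_day(records)
    pid, day = records[0].participant_id, records[0].day_index
    by_time: dict[int, list[FoodRecord]] = {}
    for r in records:
        by_time.setdefault(r.time_min, []).append(r)
    return [
        EatingOccasion(
            participant_id=pid,
            day_index=day,
            method=PRECISE,
            time_min=t,
            slot=scheme.assign_slot(t),
            grams=sum(r.grams for r in group),
            kcal=sum(r.kcal for r in group),
            n_records=len(group),
            member_times=(t,),
        )
        for t, group in sorted(by_time.items())
    ]


def build_broad_occasions(
    records: Sequence[FoodRecord], scheme: SlotScheme = DEFAULT_SCHEME
) -> list[EatingOccasion]:
    """One EO per occupied meal slot, timed at the slot representation.

    Grams/kcal are summed over everything in the slot; ``member_times``
    records the distinct precise times the slot absorbed (sorted), so
    ``n_precise_members`` >= 1 with equality iff no merging happened there.
    """
    _check_day(records)
    pid, day = records[0].participant_id, records[0].day_index
    by_slot: dict[str, list[FoodRecord]] = {}
    for r in records:
        by_slot.setdefault(scheme.assign_slot(r.time_min).name, []).append(r)
    out = []
    for name in sorted(by_slot, key=scheme.slot_order):
        group = by_slot[name]
        slot = scheme[name]
        out.append(
            EatingOccasion(
                participant_id=pid,
                day_index=day,
                method=BROAD,
                time_min=slot.rep_min,
                slot=slot,
                grams=sum(r.grams for r in group),
                kcal=sum(r.kcal for r in group),
                n_records=len(group),
                member_times=tuple(sorted({r.time_min for r in group})),
            )
        )
    return out


def build_diary_occasions(
    diary: Diary, method: str, scheme: SlotScheme = DEFAULT_SCHEME
) -> dict[int, list[EatingOccasion]]:
    """EO lists per diary day for one participant under one method."""
    builder = {PRECISE: build_precise_occasions, BROAD: build_broad_occasions}[method]
    return {day: builder(diary.day_records(day), scheme) for day in diary.days()}


def build_cohort_occasions(
    diaries: Iterable[Diary], scheme: SlotScheme = DEFAULT_SCHEME
) -> dict[str, dict[str, dict[int, list[EatingOccasion]]]]:
    """Nested method -> participant -> day -> EO list for a whole cohort."""
    out: dict[str, dict[str, dict[int, list[EatingOccasion]]]] = {
        PRECISE: {},
        BROAD: {},
    }
    for diary in diaries:
        for method in (PRECISE, BROAD):
            out[method][diary.participant_id] = build_diary_occasions(
                diary, method, scheme
            )
    return out


def occasions_to_frame(occasions: Iterable[EatingOccasion]) -> pd.DataFrame:
    """Flatten EOs to a tidy table (one row per EO) for export/inspection."""
    rows = [
        {
            "participant_id": eo.participant_id,
            "day": eo.day_index,
            "method": eo.method,
            "time_min": eo.time_min,
            "slot": eo.slot.name,
            "grams": eo.grams,
            "kcal": eo.kcal,
            "n_records": eo.n_records,
            "n_precise_members": eo.n_precise_members,
        }
        for eo in occasions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "day",
            "method",
            "time_min",
            "slot",
            "grams",
            "kcal",
            "n_records",
            "n_precise_members",
        ],
    )
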