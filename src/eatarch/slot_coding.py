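"""Broad timing scheme: fixed clock-time meal slots with representative times.

Diet-diary archives in UK cohort studies historically coded the timing of each
eating occasion (EO) into one of seven predefined meal slots rather than
keeping the exact clock time.  Each slot is an inclusive range of minutes
since midnight together with a single *representative* clock time that stands
in for every EO coded to that slot.

The default scheme is hard-coded below exactly as it appears in the source
cohort's coding documents, including two quirks that matter for downstream
bias analysis and are deliberately **not** corrected:

* the Mid-afternoon slot (14:30-16:59) is represented by 17:00, which is the
  *start of the next slot*, not the slot midpoint;
* the Evening slot (17:00-19:29) is represented by 20:00, which lies outside
  the slot entirely.

Alternative schemes (e.g. for other cultures' mealtime conventions) can be
supplied as a list of (name, start, end, representation) entries or loaded
from a YAML file; every scheme is validated to partition the full day.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class MealSlot:
    """One broad timing slot: inclusive minute range plus representative time."""

    name: str
    start_min: int
    end_min: int
    rep_min: int

    def contains(self, time_min: int) -> bool:
        return self.start_min <= time_min <= self.end_min

    @property
    def width_min(self) -> int:
        return self.end_min - self.start_min + 1


class SlotScheme:
    """An ordered set of meal slots partitioning the day [0, 1439].

    Parameters
    ----------
    slots
        Slots in chronological order.  They must tile the day with no gap or
        overlap and carry strictly increasing representative times; violations
        raise ``ValueError`` at construction.
    """

    def __init__(self, slots: Sequence[MealSlot]):
        slots = tuple(slots)
        if not slots:
            raise ValueError("slot scheme must contain at least one slot")
        expected_start = 0
        for slot in slots:
            if slot.start_min != expected_start:
                raise ValueError(
                    f"slot {slot.name!r} starts at {slot.start_min}, expected "
                    f"{expected_start}: scheme must partition the day without "
                    "gaps or overlaps"
                )
            if slot.end_min < slot.start_min:
                raise ValueError(f"slot {slot.name!r} has end before start")
            expected_start = slot.end_min + 1
        if expected_start != MINUTES_PER_DAY:
            raise ValueError(
                f"scheme covers [0, {expected_start - 1}], must cover "
                f"[0, {MINUTES_PER_DAY - 1}]"
            )
        reps = [s.rep_min for s in slots]
        if any(b <= a for a, b in zip(reps, reps[1:])):
            raise ValueError("representative times must be strictly increasing")
        names = [s.name for s in slots]
        if len(set(names)) != len(names):
            raise ValueError("slot names must be unique")
        self.slots = slots
        self._by_name = {s.name: s for s in slots}
        # minute -> slot index lookup; 1440 ints, built once
        self._index = [0] * MINUTES_PER_DAY
        for i, slot in enumerate(slots):
            for m in range(slot.start_min, slot.end_min + 1):
                self._index[m] = i

    def __len__(self) -> int:
        return len(self.slots)

    def __iter__(self):
        return iter(self.slots)

    def __getitem__(self, name: str) -> MealSlot:
        return self._by_name[name]

    def assign_slot(self, time_min: int) -> MealSlot:
        """Return the unique slot whose inclusive range contains ``time_min``."""
        t = int(time_min)
        if not 0 <= t < MINUTES_PER_DAY:
            raise ValueError(
                f"time {time_min} outside [0, {MINUTES_PER_DAY - 1}]"
            )
        return self.slots[self._index[t]]

    def slot_order(self, slot: MealSlot | str) -> int:
        """Chronological rank of a slot within the scheme (0-based)."""
        name = slot if isinstance(slot, str) else slot.name
        return self.slots.index(self._by_name[name])

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, int, int, int]]
    ) -> "SlotScheme":
        return cls([MealSlot(str(n), int(a), int(b), int(r)) for n, a, b, r in entries])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SlotScheme":
        """Load a scheme from a YAML list of {name, start, end, representation}.

        Times may be given as "HH:MM" strings or integer minutes.
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValueError("slot scheme file must contain a list of entries")
        entries = []
        for item in raw:
            try:
                entries.append(
                    (
                        item["name"],
                        parse_clock(item["start"]),
                        parse_clock(item["end"]),
                        parse_clock(item["representation"]),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise ValueError(f"malformed slot entry {item!r}") from exc
        return cls.from_entries(entries)


def parse_clock(value) -> int:
    """Convert "HH:MM" or an integer minute count to minutes since midnight."""
    if isinstance(value, int):
        return value
    text = str(value).strip()
    if ":" in text:
        hh, mm = text.split(":", 1)
        h, m = int(hh), int(mm)
        if not (0 <= m <= 59) or h < 0:
            raise ValueError(f"invalid clock time {value!r}")
        return h * 60 + m
    return int(text)


def format_clock(minutes: float) -> str:
    """Render minutes since midnight as a 24-h "HH:MM" string (rounded)."""
    m = int(round(minutes))
    return f"{m // 60:02d}:{m % 60:02d}"


def format_duration(minutes: float) -> str:
    """Render a duration in minutes as "Hh MMmin"."""
    m = int(round(minutes))
    return f"{m // 60}h {m % 60:02d}min"


#: The cohort coding scheme, verbatim: seven slots with their representative
#: clock times.  Representations are the published constants, not recomputed
#: midpoints (see module docstring for the two intentional anomalies).
DEFAULT_SCHEME = SlotScheme.from_entries(
    [
        ("Overnight", 0, 419, 360),  # Midnight-06:59 -> 06:00
        ("Breakfast", 420, 599, 480),  # 07:00-09:59 -> 08:00
        ("Mid-morning", 600, 719, 660),  # 10:00-11:59 -> 11:00
        ("Lunch", 720, 869, 780),  # 12:00-14:29 -> 13:00
        ("Mid-afternoon", 870, 1019, 1020),  # 14:30-16:59 -> 17:00
        ("Evening", 1020, 1169, 1200),  # 17:00-19:29 -> 20:00
        ("Late-evening", 1170, 1439, 1320),  # 19:30-23:59 -> 22:00
    ]
)

SLOT_NAMES = tuple(s.name for s in DEFAULT_SCHEME)


def assign_slot(time_min: int, scheme: SlotScheme = DEFAULT_SCHEME) -> MealSlot:
    """Assign a valid clock time (minutes since midnight) to its meal slot."""
    return scheme.assign_slot(time_min)


def slot_representation(slot: MealSlot | str, scheme: SlotScheme = DEFAULT_SCHEME) -> int:
    """Representative clock time (minutes) used as the broad EO time."""
    if isinstance(slot, MealSlot):
        return slot.rep_min
    return scheme[slot].rep_min
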