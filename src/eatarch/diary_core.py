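"""Domain types, diary parsing, and cohort validity rules.

A diet diary is a long-format table of food entries: one row per food per
recorded consumption time, with the participant id, diary day (1..D, default
D=3), clock time, grams and kilocalories.  Parsing keeps problem rows
visible rather than silently repairing them: a missing time is stored as
``None`` and an out-of-range time (later than 23:59) is stored as reported,
so that the exclusion rules in :func:`validate_cohort` can be applied — and
tested — exactly as documented.

Exclusion rules (applied per participant, dropping the whole participant):

1. any record with a missing consumption time;
2. any record with an invalid time (outside 00:00-23:59);
3. *partial precise data*: on some diary day the number of distinct valid
   precise times is smaller than the number of occupied meal slots among
   that day's records — an impossibility, since each occupied slot must
   contain at least one distinct precise time, indicating that precise times
   were only partially or wrongly transcribed.

Rule 3 can only fire when slot coding exists independently of the precise
time (the archival situation: diaries were slot-coded first and precise
times transcribed later).  The parser therefore accepts an optional ``slot``
column carrying the original broad coding of each record; when absent, slots
derive from the precise times and rule 3 is vacuous for diaries that survive
rules 1-2.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .slot_coding import MINUTES_PER_DAY, DEFAULT_SCHEME, SlotScheme

REQUIRED_COLUMNS = ("participant_id", "day", "time", "grams", "kcal")


@dataclass(frozen=True)
class FoodRecord:
    """One diary line: a food amount consumed at one reported time.

    ``time_min`` is minutes since midnight; ``None`` encodes a missing time
    and values outside [0, 1439] encode invalid reported times (both survive
    parsing so the exclusion rules can act on them).
    """

    participant_id: str
    day_index: int
    time_min: int | None
    grams: float
    kcal: float
    label: str | None = None
    slot_name: str | None = None  # original broad coding, if supplied

    @property
    def time_missing(self) -> bool:
        return self.time_min is None

    @property
    def time_invalid(self) -> bool:
        return self.time_min is not None and not (0 <= self.time_min < MINUTES_PER_DAY)

    @property
    def time_valid(self) -> bool:
        return not self.time_missing and not self.time_invalid


@dataclass
class Diary:
    """All records of one participant, grouped by diary day."""

    participant_id: str
    records: list[FoodRecord]
    n_days: int

    def day_records(self, day_index: int) -> list[FoodRecord]:
        return [r for r in self.records if r.day_index == day_index]

    def days(self) -> list[int]:
        return sorted({r.day_index for r in self.records})


@dataclass
class RowError:
    line: int
    message: str


@dataclass
class ValidationReport:
    """Participant-level accounting of the exclusion rules.

    ``n_input`` counts participants entering validation; the three dropped
    counts partition the exclusions (a participant is counted once, with
    missing time taking precedence over invalid time, and both over the
    partial-data rule); ``n_valid`` is what remains.  ``row_errors`` carries
    parse-time problems (malformed rows) with 1-based line numbers.
    """

    n_input: int = 0
    n_dropped_missing_time: int = 0
    n_dropped_invalid_time: int = 0
    n_dropped_partial: int = 0
    n_valid: int = 0
    row_errors: list[RowError] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.n_dropped_missing_time
            + self.n_dropped_invalid_time
            + self.n_dropped_partial
        )

    def check(self) -> None:
        counts = (
            self.n_input,
            self.n_dropped_missing_time,
            self.n_dropped_invalid_time,
            self.n_dropped_partial,
            self.n_valid,
        )
        if any(c < 0 for c in counts):
            raise ValueError("negative count in validation report")
        if self.n_valid != self.n_input - self.n_dropped:
            raise ValueError("validation report counts do not balance")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_missing_time": self.n_dropped_missing_time,
            "n_dropped_invalid_time": self.n_dropped_invalid_time,
            "n_dropped_partial": self.n_dropped_partial,
            "n_valid": self.n_valid,
            "row_errors": [
                {"line": e.line, "message": e.message} for e in self.row_errors
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _parse_time_field(text: str) -> int | None:
    """Parse the time column: "HH:MM" or integer minutes; empty -> missing.

    Out-of-range values (e.g. "24:10", 1500) parse successfully — they are
    *invalid*, not malformed, and are excluded later at cohort validation.
    """
    text = text.strip()
    if text == "" or text.upper() in {"NA", "NAN", "NONE", "MISSING"}:
        return None
    if ":" in text:
        hh, mm = text.split(":", 1)
        h, m = int(hh), int(mm)
        if h < 0 or not (0 <= m <= 59):
            raise ValueError(f"unparseable time {text!r}")
        return h * 60 + m
    return int(text)


def parse_diaries(
    source: str | Path | io.TextIOBase | Iterable[str],
    delimiter: str = ",",
) -> tuple[list[Diary], ValidationReport]:
    """Parse long-format diary CSV into one :class:`Diary` per participant.

    The source must have a header row naming at least
    ``participant_id, day, time, grams, kcal`` (an optional ``label`` column
    is carried through).  Malformed rows — non-numeric day or amounts,
    unparseable time strings, negative amounts — are skipped and recorded in
    the report's ``row_errors`` with their line number.  Missing and
    out-of-range times are *not* malformed: they parse into records and are
    handled by :func:`validate_cohort`.

    Returns diaries sorted by participant id, each with records ordered by
    (day, time); participants whose diary days are not a contiguous 1..D
    block (an empty day in the middle) are rejected with a row error.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return parse_diaries(fh, delimiter=delimiter)

    reader = csv.reader(source, delimiter=delimiter)
    report = ValidationReport()
    try:
        header = next(reader)
    except StopIteration:
        return [], report
    header = [h.strip() for h in header]
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise ValueError(f"missing mandatory column {col!r}")
    idx = {name: header.index(name) for name in header}
    has_label = "label" in idx
    has_slot = "slot" in idx

    by_participant: dict[str, list[FoodRecord]] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            pid = row[idx["participant_id"]].strip()
            if not pid:
                raise ValueError("empty participant_id")
            day = int(row[idx["day"]])
            if day < 1:
                raise ValueError(f"day index {day} < 1")
            time_min = _parse_time_field(row[idx["time"]])
            grams = float(row[idx["grams"]])
            kcal = float(row[idx["kcal"]])
            if grams < 0 or kcal < 0:
                raise ValueError("negative grams/kcal")
            label = row[idx["label"]].strip() or None if has_label else None
            slot_name = row[idx["slot"]].strip() or None if has_slot else None
        except (ValueError, IndexError) as exc:
            report.row_errors.append(RowError(lineno, str(exc)))
            continue
        by_participant.setdefault(pid, []).append(
            FoodRecord(pid, day, time_min, grams, kcal, label, slot_name)
        )

    diaries: list[Diary] = []
    for pid in sorted(by_participant):
        records = sorted(
            by_participant[pid],
            key=lambda r: (r.day_index, -1 if r.time_min is None else r.time_min),
        )
        days = sorted({r.day_index for r in records})
        n_days = days[-1]
        if days != list(range(1, n_days + 1)):
            report.row_errors.append(
                RowError(
                    0,
                    f"participant {pid!r}: diary days {days} are not a "
                    f"contiguous block 1..{n_days}; participant rejected",
                )
            )
            continue
        diaries.append(Diary(pid, records, n_days))
    report.n_input = len(diaries)
    report.n_valid = len(diaries)
    return diaries, report


def _drop_reason(diary: Diary, scheme: SlotScheme) -> str | None:
    """Classify a participant for exclusion; ``None`` means retained.

    Precedence when several rules fire: missing > invalid > partial.
    """
    if any(r.time_missing for r in diary.records):
        return "missing"
    if any(r.time_invalid for r in diary.records):
        return "invalid"
    for day in diary.days():
        recs = diary.day_records(day)
        times = {r.time_min for r in recs if r.time_valid}
        slots = set()
        for r in recs:
            if r.slot_name is not None:
                slots.add(r.slot_name)
            elif r.time_valid:
                slots.add(scheme.assign_slot(r.time_min).name)
        # each occupied slot needs >= 1 distinct precise time; fewer distinct
        # times than occupied slots means precise times were only partially
        # or wrongly transcribed, making method comparison impossible
        if len(times) < len(slots):
            return "partial"
    return None


def validate_cohort(
    diaries: Sequence[Diary],
    scheme: SlotScheme = DEFAULT_SCHEME,
    report: ValidationReport | None = None,
) -> tuple[list[Diary], ValidationReport]:
    """Apply the participant exclusion rules; return survivors and accounting.

    Drops whole participants with (a) any missing consumption time, (b) any
    invalid time (outside 00:00-23:59), or (c) partial precise data on any
    day (fewer distinct valid times than occupied meal slots).  Idempotent:
    re-validating the survivors drops nobody.
    """
    out = ValidationReport(row_errors=list(report.row_errors) if report else [])
    out.n_input = len(diaries)
    kept: list[Diary] = []
    for diary in diaries:
        reason = _drop_reason(diary, scheme)
        if reason is None:
            kept.append(diary)
        elif reason == "missing":
            out.n_dropped_missing_time += 1
        elif reason == "invalid":
            out.n_dropped_invalid_time += 1
        else:
            out.n_dropped_partial += 1
    out.n_valid = len(kept)
    out.check()
    return kept, out


def load_and_validate(
    source: str | Path | io.TextIOBase,
    scheme: SlotScheme = DEFAULT_SCHEME,
    delimiter: str = ",",
) -> tuple[list[Diary], ValidationReport]:
    """Parse then validate in one step, merging row errors into the report."""
    diaries, parse_report = parse_diaries(source, delimiter=delimiter)
    return validate_cohort(diaries, scheme=scheme, report=parse_report)
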