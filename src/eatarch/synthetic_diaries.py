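"""Synthetic 3-day child diet-diary cohorts with realistic eating structure.

The generator emulates the temporal architecture the analysis is built for:
three anchored meals (breakfast / lunch / dinner, Gaussian clock times),
a Poisson number of snacks per day placed in mid-morning, mid-afternoon or —
most often — shortly *after dinner*, with the post-dinner gap drawn from a
truncated log-normal (15-120 min, median about 30 min).  Post-dinner
snacking is the designed mechanism by which broad meal-slot coding merges
distinct eating occasions: the snack usually lands in the same Evening slot
as dinner, so the broad method undercounts frequency, inflates EO size, and
shifts last eating time and window.

Sizes are log-normal (meals larger, snacks smaller but more energy dense);
each eating occasion is emitted as 1-4 food records so that record-level
grouping is exercised.  Outcomes: TEI defaults to the participant's mean
daily kilocalories; BMI, waist circumference and the obesogenic
dietary-pattern z-score are drawn from a latent-factor model with
configurable target correlations to a chosen architecture variable (TEI may
also be switched to this mode).

Randomness uses one seed sequence per cohort, spawned per participant, so
participant ``i`` is identical whatever the cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture_metrics import day_architecture, participant_architecture
from .diary_core import Diary, FoodRecord
from .occasion_builder import build_precise_occasions
from .slot_coding import MINUTES_PER_DAY

MEAL = "meal"
SNACK = "snack"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one cohort.

    Defaults put the cohort mean at about 7 precise eating occasions per day
    (3 meals + 4 expected snacks), first eating time a few minutes past
    08:00, and a within-slot merge pattern concentrated in the evening.
    """

    n_participants: int = 100
    n_days: int = 3
    seed: int = 0
    # meal anchors: (mean minute-of-day, SD) for breakfast, lunch, dinner
    breakfast: tuple[float, float] = (484.0, 30.0)
    lunch: tuple[float, float] = (765.0, 25.0)
    dinner: tuple[float, float] = (1075.0, 35.0)
    # snack model: per-participant snack rate is gamma-distributed with mean
    # snacks_per_day (shape -> between-person spread; None/inf = no spread),
    # and daily counts are Poisson given the participant's rate
    snacks_per_day: float = 4.0
    snack_rate_shape: float | None = 8.0
    snack_placement: dict = field(
        default_factory=lambda: {
            "mid-morning": 0.20,
            "mid-afternoon": 0.30,
            "post-dinner": 0.50,
        }
    )
    midmorning_snack: tuple[float, float] = (630.0, 45.0)
    midafternoon_snack: tuple[float, float] = (945.0, 45.0)
    # post-dinner gap after dinner: log-normal, truncated to [lo, hi] minutes
    postdinner_gap_median: float = 30.0
    postdinner_gap_sigma: float = 0.6
    postdinner_gap_range: tuple[float, float] = (15.0, 120.0)
    # size model: log-normal grams (median, sigma of log) and energy density
    # kcal/g as (mean, sd), snacks denser than meals
    meal_grams: tuple[float, float] = (300.0, 0.30)
    snack_grams: tuple[float, float] = (90.0, 0.45)
    # per-participant portion-size multiplier: exp(N(0, sigma)); between-person
    # heterogeneity that real cohorts show (drives between-subject variance,
    # hence non-trivial ICCs and a TEI-size association)
    participant_size_sigma: float = 0.25
    meal_density: tuple[float, float] = (1.1, 0.15)
    snack_density: tuple[float, float] = (2.2, 0.40)
    max_records_per_eo: int = 4
    # outcome model
    tei_mode: str = "derived"  # "derived" (mean daily kcal) or "latent"
    outcome_rho: dict = field(
        default_factory=lambda: {
            "BMI": ("size_kcal", 0.10),
            "WC": ("size_kcal", 0.10),
            "ODP": ("size_g", -0.20),
        }
    )
    outcome_scale: dict = field(
        default_factory=lambda: {
            "TEI": (1700.0, 312.0),
            "BMI": (16.3, 2.1),
            "WC": (56.5, 5.3),
            "ODP": (0.0, 1.1),
        }
    )

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("invalid n_participants: must be >= 1")
        if self.n_days < 1:
            raise ValueError("invalid n_days: must be >= 1")
        if self.snacks_per_day < 0:
            raise ValueError("invalid snacks_per_day: must be >= 0")
        if self.snack_rate_shape is not None and self.snack_rate_shape <= 0:
            raise ValueError("invalid snack_rate_shape: must be > 0 or None")
        if self.participant_size_sigma < 0:
            raise ValueError("invalid participant_size_sigma: must be >= 0")
        for name, (mu, sd) in (
            ("breakfast", self.breakfast),
            ("lunch", self.lunch),
            ("dinner", self.dinner),
            ("midmorning_snack", self.midmorning_snack),
            ("midafternoon_snack", self.midafternoon_snack),
        ):
            if sd <= 0:
                raise ValueError(f"invalid {name}: SD must be > 0")
            if not 0 <= mu < MINUTES_PER_DAY:
                raise ValueError(f"invalid {name}: mean outside the day")
        probs = self.snack_placement
        if set(probs) != {"mid-morning", "mid-afternoon", "post-dinner"}:
            raise ValueError("invalid snack_placement: unexpected keys")
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ValueError("invalid snack_placement: probabilities outside [0,1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("invalid snack_placement: probabilities must sum to 1")
        lo, hi = self.postdinner_gap_range
        if not 0 < lo < hi:
            raise ValueError("invalid postdinner_gap_range")
        if self.postdinner_gap_sigma <= 0:
            raise ValueError("invalid postdinner_gap_sigma")
        if self.tei_mode not in {"derived", "latent"}:
            raise ValueError("invalid tei_mode: must be 'derived' or 'latent'")
        if self.max_records_per_eo < 1:
            raise ValueError("invalid max_records_per_eo")
        for name, (_, rho) in self.outcome_rho.items():
            if not -1 < rho < 1:
                raise ValueError(f"invalid outcome_rho[{name!r}]: |rho| must be < 1")


@dataclass(frozen=True)
class TrueOccasion:
    """Ground-truth eating event before record splitting."""

    day_index: int
    time_min: int
    kind: str  # MEAL or SNACK
    grams: float
    kcal: float


def _clip_minute(t: float) -> int:
    return int(min(max(round(t), 0), MINUTES_PER_DAY - 1))


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float
) -> float:
    # rejection sampling; acceptance region is wide for the defaults
    for _ in range(1000):
        x = float(np.exp(rng.normal(np.log(median), sigma)))
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _simulate_day(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    day: int,
    snack_rate: float,
    size_mult: float,
) -> list[TrueOccasion]:
    occasions: list[tuple[int, str]] = []
    taken: set[int] = set()

    def place(t: float) -> int:
        # eating times are distinct minutes by construction; on collision,
        # probe outward a few minutes at a time until a free minute is found
        m = _clip_minute(t)
        offset = 0
        while m in taken:
            offset += int(rng.integers(1, 4))
            if m + offset < MINUTES_PER_DAY:
                m = _clip_minute(m + offset)
            else:
                m = _clip_minute(m - offset)
        taken.add(m)
        return m

    meals = {
        "breakfast": rng.normal(*cfg.breakfast),
        "lunch": rng.normal(*cfg.lunch),
        "dinner": rng.normal(*cfg.dinner),
    }
    dinner_min = None
    for name in ("breakfast", "lunch", "dinner"):
        m = place(meals[name])
        if name == "dinner":
            dinner_min = m
        occasions.append((m, MEAL))

    n_snacks = int(rng.poisson(snack_rate))
    names = list(cfg.snack_placement)
    probs = np.array([cfg.snack_placement[n] for n in names])
    last_evening_event = float(dinner_min)
    for _ in range(n_snacks):
        where = names[int(rng.choice(len(names), p=probs))]
        if where == "mid-morning":
            t = rng.normal(*cfg.midmorning_snack)
        elif where == "mid-afternoon":
            t = rng.normal(*cfg.midafternoon_snack)
        else:
            # post-dinner snacks chain: each gap is measured from the
            # previous evening eating event, so consecutive intervals
            # follow the configured gap distribution
            gap = _truncated_lognormal(
                rng,
                cfg.postdinner_gap_median,
                cfg.postdinner_gap_sigma,
                *cfg.postdinner_gap_range,
            )
            t = last_evening_event + gap
            last_evening_event = t
        occasions.append((place(t), SNACK))

    out = []
    for time_min, kind in sorted(occasions):
        g_med, g_sig = cfg.meal_grams if kind == MEAL else cfg.snack_grams
        d_mu, d_sd = cfg.meal_density if kind == MEAL else cfg.snack_density
        grams = size_mult * float(np.exp(rng.normal(np.log(g_med), g_sig)))
        density = float(max(rng.normal(d_mu, d_sd), 0.2))
        out.append(TrueOccasion(day, time_min, kind, grams, grams * density))
    return out


def _split_records(
    rng: np.random.Generator, pid: str, occ: TrueOccasion, max_records: int
) -> list[FoodRecord]:
    n = int(rng.integers(1, max_records + 1))
    if n == 1:
        shares = np.array([1.0])
    else:
        shares = rng.dirichlet(np.ones(n) * 2.0)
    return [
        FoodRecord(
            participant_id=pid,
            day_index=occ.day_index,
            time_min=occ.time_min,
            grams=occ.grams * s,
            kcal=occ.kcal * s,
            label=occ.kind,
        )
        for s in shares
    ]


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[Diary], pd.DataFrame, dict]:
    """Simulate a cohort: diaries, outcome table, and ground truth.

    Returns ``(diaries, outcomes, truth)`` where ``truth`` maps participant
    id to its per-day list of true eating occasions (time, kind, grams,
    kcal) — the oracle for grouping tests.  Deterministic given
    ``cfg.seed``; participant streams are spawned independently, so the
    first ``n`` participants are identical across cohort sizes.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    diaries: list[Diary] = []
    truth: dict[str, dict[int, list[TrueOccasion]]] = {}
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i,)))
        pid = f"S{i + 1:06d}"
        if cfg.snack_rate_shape is None or cfg.snacks_per_day == 0:
            snack_rate = cfg.snacks_per_day
        else:
            snack_rate = float(
                rng.gamma(cfg.snack_rate_shape, cfg.snacks_per_day / cfg.snack_rate_shape)
            )
        size_mult = (
            float(np.exp(rng.normal(0.0, cfg.participant_size_sigma)))
            if cfg.participant_size_sigma > 0
            else 1.0
        )
        records: list[FoodRecord] = []
        per_day: dict[int, list[TrueOccasion]] = {}
        for day in range(1, cfg.n_days + 1):
            occs = _simulate_day(rng, cfg, day, snack_rate, size_mult)
            per_day[day] = occs
            for occ in occs:
                records.extend(_split_records(rng, pid, occ, cfg.max_records_per_eo))
        records.sort(key=lambda r: (r.day_index, r.time_min))
        diaries.append(Diary(pid, records, cfg.n_days))
        truth[pid] = per_day

    outcomes = _generate_outcomes(cfg, diaries, root)
    return diaries, outcomes, {
        pid: {
            day: [
                {
                    "time_min": o.time_min,
                    "kind": o.kind,
                    "grams": o.grams,
                    "kcal": o.kcal,
                }
                for o in occs
            ]
            for day, occs in per_day.items()
        }
        for pid, per_day in truth.items()
    }


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _generate_outcomes(
    cfg: SyntheticConfig, diaries: Sequence[Diary], root: np.random.SeedSequence
) -> pd.DataFrame:
    """Outcome table keyed by participant, correlated with true architecture.

    Latent outcomes are ``rho * z(variable) + sqrt(1-rho^2) * noise`` scaled
    to the configured mean/SD, where the variable is the participant's
    precise-method architecture value — so a configured rho is the target
    correlation against what the pipeline itself will measure.
    """
    arch_rows = []
    for diary in diaries:
        days = [
            day_architecture(build_precise_occasions(diary.day_records(d)))
            for d in diary.days()
        ]
        arch_rows.append(participant_architecture(days))
    frame = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in arch_rows],
            "size_g": [p.size_g for p in arch_rows],
            "size_kcal": [p.size_kcal for p in arch_rows],
            "frequency": [p.frequency for p in arch_rows],
            "first_min": [p.first_min for p in arch_rows],
            "last_min": [p.last_min for p in arch_rows],
            "window_min": [p.window_min for p in arch_rows],
            "interval_min": [p.interval_min for p in arch_rows],
        }
    )
    # mean daily kcal per participant, for derived TEI
    daily_kcal = np.array(
        [
            np.mean(
                [sum(r.kcal for r in diary.day_records(d)) for d in diary.days()]
            )
            for diary in diaries
        ]
    )
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1 << 20,)))
    out = pd.DataFrame({"participant_id": frame["participant_id"]})

    def latent(variable: str, rho: float, mean: float, sd: float) -> np.ndarray:
        z = _standardize(frame[variable].to_numpy())
        eps = rng.standard_normal(len(z))
        y = rho * z + np.sqrt(1.0 - rho**2) * eps
        return mean + sd * y

    if cfg.tei_mode == "derived" and "TEI" not in cfg.outcome_rho:
        out["TEI"] = daily_kcal
    for name, (variable, rho) in cfg.outcome_rho.items():
        mean, sd = cfg.outcome_scale.get(name, (0.0, 1.0))
        out[name] = latent(variable, rho, mean, sd)
    for name in ("TEI", "BMI", "WC", "ODP"):
        if name not in out.columns:
            mean, sd = cfg.outcome_scale.get(name, (0.0, 1.0))
            out[name] = mean + sd * rng.standard_normal(len(out))
    return out


def corrupt_times(
    diaries: Sequence[Diary],
    missing_rate: float = 0.0,
    invalid_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Diary], pd.DataFrame]:
    """Inject missing and invalid consumption times; return the tamper log.

    Each record is independently set to a missing time with probability
    ``missing_rate``, else to an invalid time (past 23:59) with probability
    ``invalid_rate``.  The log has one row per tampered record
    (participant_id, day, record_index, original time, kind of tampering),
    enabling exact reconciliation with downstream validation counts.
    """
    if not 0 <= missing_rate < 1 or not 0 <= invalid_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[Diary] = []
    log_rows = []
    for diary in diaries:
        new_records = []
        for j, rec in enumerate(diary.records):
            u = rng.uniform()
            if u < missing_rate:
                new_records.append(replace(rec, time_min=None))
                log_rows.append(
                    {
                        "participant_id": diary.participant_id,
                        "day": rec.day_index,
                        "record_index": j,
                        "original_time_min": rec.time_min,
                        "kind": "missing",
                    }
                )
            elif u < missing_rate + invalid_rate:
                bad = MINUTES_PER_DAY + int(rng.integers(0, 120))
                new_records.append(replace(rec, time_min=bad))
                log_rows.append(
                    {
                        "participant_id": diary.participant_id,
                        "day": rec.day_index,
                        "record_index": j,
                        "original_time_min": rec.time_min,
                        "kind": "invalid",
                    }
                )
            else:
                new_records.append(rec)
        out.append(Diary(diary.participant_id, new_records, diary.n_days))
    log = pd.DataFrame(
        log_rows,
        columns=["participant_id", "day", "record_index", "original_time_min", "kind"],
    )
    return out, log


def diaries_to_frame(diaries: Sequence[Diary]) -> pd.DataFrame:
    """Flatten diaries to the long CSV schema the parser reads."""
    rows = []
    for diary in diaries:
        for r in diary.records:
            if r.time_min is None:
                time = ""
            else:
                time = f"{r.time_min // 60:02d}:{r.time_min % 60:02d}"
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "day": r.day_index,
                    "time": time,
                    "grams": round(r.grams, 3),
                    "kcal": round(r.kcal, 3),
                    "label": r.label or "",
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "day", "time", "grams", "kcal", "label"]
    )


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1), encoding="utf-8")
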