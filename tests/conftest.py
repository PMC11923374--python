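"""Shared fixtures: tiny hand-checkable diaries and a seeded synthetic cohort."""

from __future__ import annotations

import io

import pytest

import eatarch as ea


@pytest.fixture
def simple_csv():
    """Two participants, hand-enumerable structure."""
    return io.StringIO(
        "participant_id,day,time,grams,kcal\n"
        "P1,1,08:00,100,150\n"
        "P1,1,08:00,50,60\n"
        "P1,1,10:30,30,80\n"
        "P1,1,13:00,250,300\n"
        "P1,2,07:45,120,140\n"
        "P1,2,12:30,200,250\n"
        "P1,2,18:00,300,400\n"
        "P2,1,09:15,80,90\n"
        "P2,1,17:10,100,120\n"
        "P2,1,19:00,50,110\n"
    )


@pytest.fixture
def simple_diaries(simple_csv):
    diaries, report = ea.parse_diaries(simple_csv)
    assert not report.row_errors
    return diaries


def _records(pid, day, entries):
    return [
        ea.FoodRecord(pid, day, t, g, k) for t, g, k in entries
    ]


@pytest.fixture
def make_records():
    return _records


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate synthetic cohort under generator defaults (seeded)."""
    cfg = ea.SyntheticConfig(n_participants=120, seed=42)
    diaries, outcomes, truth = ea.generate_cohort(cfg)
    return cfg, diaries, outcomes, truth


@pytest.fixture(scope="session")
def default_architecture(default_cohort):
    _, diaries, _, _ = default_cohort
    occasions = ea.build_cohort_occasions(diaries)
    return occasions, ea.cohort_architecture(occasions)
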