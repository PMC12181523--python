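"""Shared fixtures: the printed worked-example day and small synthetic studies."""

from __future__ import annotations

from datetime import datetime

import pytest

from somnoprot import SimulationConfig, SleepEpisode, simulate_study
from somnoprot.io import pivot_npx


def make_episode(pid, start, end, *, awake=0):
    """Episode fully asleep except ``awake`` minutes (light absorbs the rest)."""
    span = int((end - start).total_seconds() // 60)
    tst = span - awake
    light = tst - 2 * (tst // 3)
    deep = tst // 3
    rem = tst // 3
    return SleepEpisode(pid, start, end, light, deep, rem, awake)


@pytest.fixture
def fig_day_episodes():
    """The worked-example day: nocturnal main sleep plus three naps.

    Intervals 22:00-04:00, 04:30-06:30, 10:30-11:30, 15:00-17:00, all
    minutes asleep; expected main 6 h, secondary 5 h, daytime 3 h,
    morning 1 h, afternoon 2 h.
    """
    return [
        make_episode("P1", datetime(2022, 11, 1, 22, 0), datetime(2022, 11, 2, 4, 0)),
        make_episode("P1", datetime(2022, 11, 2, 4, 30), datetime(2022, 11, 2, 6, 30)),
        make_episode("P1", datetime(2022, 11, 2, 10, 30), datetime(2022, 11, 2, 11, 30)),
        make_episode("P1", datetime(2022, 11, 2, 15, 0), datetime(2022, 11, 2, 17, 0)),
    ]


@pytest.fixture(scope="session")
def small_study():
    """A compact end-to-end study: 30 participants, 95 days, 40 assays."""
    cfg = SimulationConfig(
        n_participants=30,
        n_days=95,
        seed=42,
        n_assays=40,
        n_duplicate_proteins=4,
        n_signal_assays=6,
        n_decoy_terms=10,
        planted_term_size=8,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def cohort_study():
    """A study at the cohort's scale: 77 participants, 368 assays."""
    cfg = SimulationConfig(n_participants=77, n_days=120, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def cohort_npx(cohort_study):
    npx, _ = pivot_npx(cohort_study.npx_long)
    return npx
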