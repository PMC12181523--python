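"""Episode logs -> per-participant sleep phenotypes.

The phenotyping stage turns device-logged sleep episodes into daily
records and then per-participant averages:

1. each episode is assigned to the calendar date of its end (wake) time,
   so a 22:00-04:00 nocturnal sleep lands on the same day as the naps
   that follow it;
2. within a day, the episode with the largest total sleep time (TST =
   light + deep + REM minutes, awake excluded) is the *main* sleep; all
   others are *secondary*;
3. secondary episodes lying in the 09:00-19:00 window are *daytime*
   sleep, split into *morning* (ending by noon) and *afternoon*
   (starting at or after noon);
4. days with a 24-h TST under 2 h are dropped, and participants with
   fewer than 90 surviving days are excluded;
5. the remaining days are averaged per participant and the averages
   standardized across the cohort (z-scores, n-1 denominator).

Worked example: a day built from episodes 22:00-04:00, 04:30-06:30,
10:30-11:30 and 15:00-17:00 (all minutes asleep) yields main 6 h,
secondary 5 h, daytime 3 h, morning 1 h, afternoon 2 h — the 04:30
episode counts toward secondary TST but lies outside every sub-window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SleepEpisode

__all__ = [
    "DayRecord",
    "SleepPhenotype",
    "episode_tst",
    "assign_days",
    "classify_day",
    "build_day_records",
    "apply_qc",
    "summarize",
    "standardize",
    "standardize_phenotypes",
    "phenotypes_to_frame",
]

DAYTIME_START = time(9, 0)
DAYTIME_END = time(19, 0)
NOON = time(12, 0)

#: QC defaults: drop days with 24-h TST under 2 h, keep participants with
#: at least 90 surviving days.
MIN_DAILY_TST_MIN = 120
MIN_VALID_DAYS = 90

DayRule = Literal["wake-date", "noon-noon"]
MainRule = Literal["tst", "span"]

PHENOTYPE_FIELDS = (
    "avg_tst_24h",
    "avg_main_tst",
    "avg_secondary_tst",
    "avg_daytime_tst",
    "avg_morning_tst",
    "avg_afternoon_tst",
)


@dataclass
class DayRecord:
    """One participant-day with labelled episodes and TST tallies (minutes)."""

    participant_id: str
    day: date
    episodes: list[SleepEpisode]
    labels: list[str]  # per-episode: "main" or "secondary"
    tst_24h: int
    main_tst: int
    secondary_tst: int
    daytime_tst: int
    morning_tst: int
    afternoon_tst: int


@dataclass
class SleepPhenotype:
    """Per-participant daily-average sleep durations (minutes/day)."""

    participant_id: str
    n_valid_days: int
    avg_tst_24h: float
    avg_main_tst: float
    avg_secondary_tst: float
    avg_daytime_tst: float
    avg_morning_tst: float
    avg_afternoon_tst: float
    z_secondary: float | None = None
    z_daytime: float | None = None
    z_afternoon: float | None = None


def episode_tst(episode: SleepEpisode) -> int:
    """Total sleep time of one episode: asleep stage minutes, awake excluded."""
    return episode.light_min + episode.deep_min + episode.rem_min


def _episode_day(ep: SleepEpisode, rule: DayRule) -> date:
    if rule == "wake-date":
        return ep.end.date()
    if rule == "noon-noon":
        # an episode belongs to the noon-to-noon window containing its end;
        # windows are labelled by the date they start on
        d = ep.end.date()
        return d if ep.end.time() >= NOON else d - timedelta(days=1)
    raise ValueError(f"unknown day rule {rule!r}")


def assign_days(
    episodes: Sequence[SleepEpisode], *, day_rule: DayRule = "wake-date"
) -> dict[tuple[str, date], list[SleepEpisode]]:
    """Group episodes into participant-days; episodes are never split.

    Episodes of one participant must not overlap in time.
    """
    by_participant: dict[str, list[SleepEpisode]] = {}
    for ep in episodes:
        by_participant.setdefault(ep.participant_id, []).append(ep)
    out: dict[tuple[str, date], list[SleepEpisode]] = {}
    for pid, eps in by_participant.items():
        eps = sorted(eps, key=lambda e: e.start)
        for prev, nxt in zip(eps, eps[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping episodes for participant {pid}: "
                    f"[{prev.start.isoformat()}, {prev.end.isoformat()}] and "
                    f"[{nxt.start.isoformat()}, {nxt.end.isoformat()}]"
                )
        for ep in eps:
            out.setdefault((pid, _episode_day(ep, day_rule)), []).append(ep)
    return out


def classify_day(
    participant_id: str,
    day: date,
    episodes: Sequence[SleepEpisode],
    *,
    main_rule: MainRule = "tst",
) -> DayRecord:
    """Label one day's episodes as main/secondary and tally window TSTs.

    The main episode is the longest by TST (configurable to wall-clock
    span); ties break to the earliest start. Daytime/morning/afternoon
    labels attach only to secondary episodes whose start lies on the
    assigned day: daytime means start >= 09:00 and end < 19:00, morning
    additionally end <= noon, afternoon additionally start >= noon.
    """
    if not episodes:
        raise ValueError("classify_day requires at least one episode")
    eps = sorted(episodes, key=lambda e: e.start)
    size = episode_tst if main_rule == "tst" else (lambda e: e.span_min)
    if main_rule not in ("tst", "span"):
        raise ValueError(f"unknown main rule {main_rule!r}")
    main_idx = max(range(len(eps)), key=lambda i: (size(eps[i]), -i))
    # max with key (size, -i) prefers the earliest start on ties because
    # eps is start-sorted and -i decreases with later episodes
    labels = ["secondary"] * len(eps)
    labels[main_idx] = "main"

    main_tst = episode_tst(eps[main_idx])
    secondary = daytime = morning = afternoon = 0
    for i, ep in enumerate(eps):
        if i == main_idx:
            continue
        t = episode_tst(ep)
        secondary += t
        on_day = ep.start.date() == day and ep.end.date() == day
        if on_day and ep.start.time() >= DAYTIME_START and ep.end.time() < DAYTIME_END:
            daytime += t
            if ep.end.time() <= NOON:
                morning += t
            elif ep.start.time() >= NOON:
                afternoon += t
            # an episode straddling noon is daytime-only
    return DayRecord(
        participant_id=participant_id,
        day=day,
        episodes=eps,
        labels=labels,
        tst_24h=main_tst + secondary,
        main_tst=main_tst,
        secondary_tst=secondary,
        daytime_tst=daytime,
        morning_tst=morning,
        afternoon_tst=afternoon,
    )


def build_day_records(
    episodes: Sequence[SleepEpisode],
    *,
    day_rule: DayRule = "wake-date",
    main_rule: MainRule = "tst",
) -> list[DayRecord]:
    """Convenience: assign days then classify each, sorted by (pid, day)."""
    grouped = assign_days(episodes, day_rule=day_rule)
    records = [
        classify_day(pid, day, eps, main_rule=main_rule)
        for (pid, day), eps in grouped.items()
    ]
    records.sort(key=lambda r: (r.participant_id, r.day))
    return records


def apply_qc(
    day_records: Sequence[DayRecord],
    *,
    min_daily_tst: int = MIN_DAILY_TST_MIN,
    min_days: int = MIN_VALID_DAYS,
) -> tuple[list[DayRecord], dict]:
    """Drop low-TST days, then participants with too few surviving days.

    A day is dropped when its 24-h TST is strictly below ``min_daily_tst``
    (the 2-h rule: 119 min is dropped, 120 retained); a participant is
    dropped when fewer than ``min_days`` days survive.
    """
    dropped_days: list[tuple[str, date]] = []
    per_participant: dict[str, list[DayRecord]] = {}
    for rec in day_records:
        if rec.tst_24h < min_daily_tst:
            dropped_days.append((rec.participant_id, rec.day))
        else:
            per_participant.setdefault(rec.participant_id, []).append(rec)
    excluded = [
        pid for pid, recs in per_participant.items() if len(recs) < min_days
    ]
    kept = [
        rec
        for pid, recs in per_participant.items()
        if pid not in excluded
        for rec in recs
    ]
    kept.sort(key=lambda r: (r.participant_id, r.day))
    report = {
        "n_input_days": len(day_records),
        "n_dropped_days": len(dropped_days),
        "dropped_days": dropped_days,
        "excluded_participants": sorted(excluded),
        "n_retained_days": len(kept),
    }
    return kept, report


def summarize(day_records: Sequence[DayRecord]) -> list[SleepPhenotype]:
    """Average day-level TSTs per participant over their valid days.

    Days with zero secondary sleep contribute zeros to the secondary
    average rather than being dropped.
    """
    per: dict[str, list[DayRecord]] = {}
    for rec in day_records:
        per.setdefault(rec.participant_id, []).append(rec)
    out = []
    for pid in sorted(per):
        recs = per[pid]
        n = len(recs)
        out.append(
            SleepPhenotype(
                participant_id=pid,
                n_valid_days=n,
                avg_tst_24h=sum(r.tst_24h for r in recs) / n,
                avg_main_tst=sum(r.main_tst for r in recs) / n,
                avg_secondary_tst=sum(r.secondary_tst for r in recs) / n,
                avg_daytime_tst=sum(r.daytime_tst for r in recs) / n,
                avg_morning_tst=sum(r.morning_tst for r in recs) / n,
                avg_afternoon_tst=sum(r.afternoon_tst for r in recs) / n,
            )
        )
    return out


def standardize(values) -> np.ndarray:
    """z-score a vector: subtract the mean, divide by the SD (n-1).

    Raises on fewer than two values or a zero SD (degenerate cohort).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "cannot standardize a constant vector; the cohort is degenerate "
            "in this phenotype"
        )
    return (x - x.mean()) / sd


_Z_FIELDS = {
    "avg_secondary_tst": "z_secondary",
    "avg_daytime_tst": "z_daytime",
    "avg_afternoon_tst": "z_afternoon",
}


def standardize_phenotypes(
    phenotypes: Sequence[SleepPhenotype],
    fields: Iterable[str] = _Z_FIELDS,
) -> list[SleepPhenotype]:
    """Populate cohort-level z-scores for the requested average fields."""
    for f in fields:
        if f not in _Z_FIELDS:
            raise ValueError(f"no z-score slot for field {f!r}")
        z = standardize([getattr(p, f) for p in phenotypes])
        for p, zi in zip(phenotypes, z):
            setattr(p, _Z_FIELDS[f], float(zi))
    return list(phenotypes)


def phenotypes_to_frame(phenotypes: Sequence[SleepPhenotype]) -> pd.DataFrame:
    """Tabulate phenotypes as a DataFrame indexed by participant_id."""
    rows = {
        p.participant_id: {
            "n_valid_days": p.n_valid_days,
            **{f: getattr(p, f) for f in PHENOTYPE_FIELDS},
            "z_secondary": p.z_secondary,
            "z_daytime": p.z_daytime,
            "z_afternoon": p.z_afternoon,
        }
        for p in phenotypes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df
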