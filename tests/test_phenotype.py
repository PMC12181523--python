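"""Sleep phenotyping: day assignment, main/secondary labels, QC, averaging."""

from __future__ import annotations

import random
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from somnoprot import (
    SleepEpisode,
    apply_qc,
    assign_days,
    build_day_records,
    classify_day,
    episode_tst,
    standardize,
    summarize,
)
from somnoprot.phenotype import phenotypes_to_frame, standardize_phenotypes

from conftest import make_episode


class TestEpisodeTST:
    def test_main_episode_excluding_awake(self):
        ep = SleepEpisode("P1", datetime(2022, 11, 1, 22, 0),
                          datetime(2022, 11, 2, 4, 0), 200, 80, 80, 0)
        assert episode_tst(ep) == 360

    def test_fully_awake_episode_has_zero_tst(self):
        ep = SleepEpisode("P1", datetime(2022, 11, 1, 22, 0),
                          datetime(2022, 11, 1, 23, 0), 0, 0, 0, 60)
        assert episode_tst(ep) == 0

    def test_stage_sum(self):
        ep = SleepEpisode("P1", datetime(2022, 11, 1, 22, 0),
                          datetime(2022, 11, 1, 23, 15), 30, 20, 10, 15)
        assert episode_tst(ep) == 60


class TestAssignDays:
    def test_worked_example_four_episodes_one_day(self, fig_day_episodes):
        grouped = assign_days(fig_day_episodes)
        assert set(grouped) == {("P1", date(2022, 11, 2))}
        assert len(grouped[("P1", date(2022, 11, 2))]) == 4

    def test_episode_within_one_evening_stays_on_that_date(self):
        ep = make_episode("P1", datetime(2022, 11, 1, 22, 0),
                          datetime(2022, 11, 1, 23, 30))
        assert list(assign_days([ep])) == [("P1", date(2022, 11, 1))]

    def test_midnight_crossing_episode_follows_wake_date(self):
        ep = make_episode("P1", datetime(2022, 11, 1, 23, 30),
                          datetime(2022, 11, 2, 1, 30))
        assert list(assign_days([ep])) == [("P1", date(2022, 11, 2))]

    def test_overlapping_episodes_rejected(self):
        eps = [
            make_episode("P1", datetime(2022, 11, 1, 22, 0), datetime(2022, 11, 2, 4, 0)),
            make_episode("P1", datetime(2022, 11, 2, 3, 0), datetime(2022, 11, 2, 5, 0)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            assign_days(eps)

    def test_noon_noon_rule_groups_nocturnal_sleep_with_prior_day(self):
        ep = make_episode("P1", datetime(2022, 11, 1, 22, 0),
                          datetime(2022, 11, 2, 4, 0))
        assert list(assign_days([ep], day_rule="noon-noon")) == [
            ("P1", date(2022, 11, 1))
        ]


class TestClassifyDay:
    def test_worked_example_tst_breakdown(self, fig_day_episodes):
        rec = classify_day("P1", date(2022, 11, 2), fig_day_episodes)
        assert rec.main_tst == 360
        assert rec.secondary_tst == 300
        assert rec.daytime_tst == 180
        assert rec.morning_tst == 60
        assert rec.afternoon_tst == 120
        assert rec.tst_24h == 660

    def test_single_episode_day_is_all_main(self):
        ep = make_episode("P1", datetime(2022, 11, 1, 22, 0),
                          datetime(2022, 11, 2, 4, 0))
        rec = classify_day("P1", date(2022, 11, 2), [ep])
        assert rec.labels == ["main"]
        assert rec.secondary_tst == 0

    def test_equal_tst_tie_breaks_to_earliest_start(self):
        # two 2-h fully-asleep episodes at 01:00 and 13:00; enumerate both
        # possible assignments and check the stated rule picks the earlier
        a = make_episode("P1", datetime(2022, 11, 2, 1, 0), datetime(2022, 11, 2, 3, 0))
        b = make_episode("P1", datetime(2022, 11, 2, 13, 0), datetime(2022, 11, 2, 15, 0))
        assert episode_tst(a) == episode_tst(b)
        for order in ([a, b], [b, a]):
            rec = classify_day("P1", date(2022, 11, 2), order)
            main = rec.episodes[rec.labels.index("main")]
            assert main.start == a.start

    def test_noon_straddling_secondary_is_daytime_only(self):
        main = make_episode("P1", datetime(2022, 11, 1, 22, 0),
                            datetime(2022, 11, 2, 4, 0))
        straddle = make_episode("P1", datetime(2022, 11, 2, 11, 0),
                                datetime(2022, 11, 2, 13, 0))
        rec = classify_day("P1", date(2022, 11, 2), [main, straddle])
        assert rec.daytime_tst == 120
        assert rec.morning_tst == 0
        assert rec.afternoon_tst == 0

    def test_main_in_daytime_window_not_counted_as_daytime(self):
        # a long daytime main plus a short evening nap: daytime TST counts
        # only secondary episodes
        main = make_episode("P1", datetime(2022, 11, 2, 10, 0),
                            datetime(2022, 11, 2, 16, 0))
        nap = make_episode("P1", datetime(2022, 11, 2, 20, 0),
                           datetime(2022, 11, 2, 21, 0))
        rec = classify_day("P1", date(2022, 11, 2), [main, nap])
        assert rec.labels[rec.episodes.index(main)] == "main"
        assert rec.daytime_tst == 0
        assert rec.secondary_tst == 60

    def test_window_boundaries(self):
        main = make_episode("P1", datetime(2022, 11, 1, 22, 0),
                            datetime(2022, 11, 2, 4, 0))
        ends_at_19 = make_episode("P1", datetime(2022, 11, 2, 17, 30),
                                  datetime(2022, 11, 2, 19, 0))
        rec = classify_day("P1", date(2022, 11, 2), [main, ends_at_19])
        assert rec.daytime_tst == 0  # "ending before 19:00" is strict
        ends_at_noon = make_episode("P1", datetime(2022, 11, 2, 10, 0),
                                    datetime(2022, 11, 2, 12, 0))
        rec = classify_day("P1", date(2022, 11, 2), [main, ends_at_noon])
        assert rec.morning_tst == 120
        assert rec.afternoon_tst == 0

    def test_invariants_and_permutation_invariance_on_random_days(self):
        rng = random.Random(7)
        base = date(2022, 11, 2)
        for _ in range(25):
            eps, cursor = [], datetime(2022, 11, 1, 20, 0)
            for _k in range(rng.randint(1, 5)):
                start = cursor + timedelta(minutes=rng.randint(10, 180))
                span = rng.randint(60, 300)
                end = start + timedelta(minutes=span)
                awake = rng.randint(0, span // 4)
                eps.append(make_episode("P1", start, end, awake=awake))
                cursor = end
            rec = classify_day("P1", base, eps)
            assert rec.main_tst + rec.secondary_tst == rec.tst_24h
            assert rec.morning_tst + rec.afternoon_tst <= rec.daytime_tst
            assert rec.daytime_tst <= rec.secondary_tst
            assert sorted(rec.labels).count("main") == 1
            shuffled = eps[:]
            rng.shuffle(shuffled)
            rec2 = classify_day("P1", base, shuffled)
            assert (rec2.main_tst, rec2.secondary_tst, rec2.daytime_tst,
                    rec2.morning_tst, rec2.afternoon_tst) == (
                rec.main_tst, rec.secondary_tst, rec.daytime_tst,
                rec.morning_tst, rec.afternoon_tst)


def _day(pid, d, tst):
    # minimal single-episode day with the requested 24-h TST
    start = datetime(d.year, d.month, d.day, 0, 0)
    return classify_day(
        pid, d, [make_episode(pid, start, start + timedelta(minutes=max(tst, 60)),
                              awake=max(60 - tst, 0))]
    )


class TestQC:
    def test_two_hour_day_boundary_is_strict(self):
        d1 = _day("P1", date(2022, 11, 1), 119)
        d2 = _day("P1", date(2022, 11, 2), 120)
        kept, report = apply_qc([d1, d2], min_days=1)
        assert [r.day for r in kept] == [date(2022, 11, 2)]
        assert report["n_dropped_days"] == 1

    def test_90_day_participant_boundary(self):
        days_89 = [_day("P1", date(2022, 11, 1) + timedelta(days=i), 400)
                   for i in range(89)]
        days_90 = [_day("P2", date(2022, 11, 1) + timedelta(days=i), 400)
                   for i in range(90)]
        kept, report = apply_qc(days_89 + days_90)
        assert {r.participant_id for r in kept} == {"P2"}
        assert report["excluded_participants"] == ["P1"]

    def test_empty_input(self):
        kept, report = apply_qc([])
        assert kept == [] and report["n_input_days"] == 0


class TestSummarize:
    def test_single_worked_example_day(self, fig_day_episodes):
        recs = build_day_records(fig_day_episodes)
        phen = summarize(recs)
        assert phen[0].avg_secondary_tst == 300
        assert phen[0].n_valid_days == 1

    def test_zero_secondary_days_average_to_zero(self):
        recs = [_day("P1", date(2022, 11, 1) + timedelta(days=i), 400)
                for i in range(3)]
        assert summarize(recs)[0].avg_secondary_tst == 0

    def test_zero_days_count_in_denominator(self, fig_day_episodes):
        quiet = _day("P1", date(2022, 11, 3), 400)
        recs = build_day_records(fig_day_episodes) + [quiet]
        assert summarize(recs)[0].avg_secondary_tst == 150


class TestStandardize:
    def test_two_point_closed_form(self):
        z = standardize([1.0, 3.0])
        assert z == pytest.approx([-0.7071067811865475, 0.7071067811865475])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([2.0, 2.0, 2.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        z = standardize(rng.normal(50, 9, 200))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_phenotype_z_fields_populated(self, fig_day_episodes):
        other = _day("P2", date(2022, 11, 2), 400)
        phen = summarize(build_day_records(fig_day_episodes) + [other])
        standardize_phenotypes(phen)
        df = phenotypes_to_frame(phen)
        assert df["z_secondary"].mean() == pytest.approx(0.0, abs=1e-12)


class TestAgainstGenerator:
    def test_phenotyper_recovers_generator_main_sleep_means(self, small_study):
        # per-participant average main TST must sit near the planted mean
        df = small_study.phenotypes
        truth = small_study.truth.true_main_mean
        err = [df.loc[p, "avg_main_tst"] - truth[p] for p in df.index]
        # daily SD ~28 min over >=90 days -> SE ~3 min
        assert np.max(np.abs(err)) < 12.0
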