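"""Non-wear detection, inclusion rules, averaging and composition building."""

import numpy as np
import pandas as pd
import pytest

import coda24 as c
from coda24.preprocessing import (
    SurveyRecord,
    average_wake_behaviours,
    day_is_valid,
    read_daily_csv,
    read_survey_csv,
    records_to_frame,
)


def make_day(child_id="k1", date="d1", weekend=False, wear=600.0,
             sed=290.0, lg=230.0, walk=20.0, run=10.0, mvg=10.0):
    return c.DayRecord(child_id=child_id, date=date, is_weekend=weekend,
                       wear_min=wear, sedentary_min=sed, light_games_min=lg,
                       walking_min=walk, running_min=run, mv_games_min=mvg)


def make_survey(child_id="k1", screen=840.0, quiet=420.0, sdq=None, **kw):
    sdq = sdq or {"emotional": 2, "conduct": 1, "hyperactivity": 3,
                  "peer": 1, "prosocial": 8}
    defaults = dict(sleep_night_min=620.0, sleep_day_min=70.0,
                    age_years=3.5, sex="female", parent_education="tertiary")
    defaults.update(kw)
    return SurveyRecord(child_id=child_id, screen_weekly_min=screen,
                        quiet_weekly_min=quiet, sdq=sdq, **defaults)


class TestDetectNonwear:
    def test_long_low_run_detected(self):
        s = np.full(200, 40.0)
        s[60:105] = 5.0  # 45 min below threshold
        assert c.detect_nonwear(s) == [(60, 105)]

    def test_short_run_ignored(self):
        s = np.full(200, 40.0)
        s[60:89] = 5.0  # 29 min: under the 30-min minimum
        assert c.detect_nonwear(s) == []

    def test_threshold_is_strict(self):
        s = np.full(120, 13.0)  # exactly at threshold: worn
        assert c.detect_nonwear(s) == []
        assert c.detect_nonwear(np.full(120, 12.999)) == [(0, 120)]

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            c.detect_nonwear(np.array([-1.0] * 40))

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(25):
            s = rng.choice([5.0, 40.0], size=1440, p=[0.4, 0.6])
            got = c.detect_nonwear(s)
            # oracle: linear scan over maximal below-threshold runs
            expected, start = [], None
            for i, v in enumerate(s):
                if v < 13.0 and start is None:
                    start = i
                elif v >= 13.0 and start is not None:
                    if i - start >= 30:
                        expected.append((start, i))
                    start = None
            if start is not None and len(s) - start >= 30:
                expected.append((start, len(s)))
            assert got == expected


class TestWearCriteria:
    @pytest.mark.parametrize("wear, valid", [(480, True), (479, False),
                                             (1440, True)])
    def test_day_validity_threshold(self, wear, valid):
        day = make_day(wear=wear, sed=200.0, lg=150.0, walk=20.0, run=10.0,
                       mvg=10.0)
        assert day_is_valid(day) is valid

    @pytest.mark.parametrize("n_weekday, n_weekend, ok", [
        (3, 1, True), (4, 0, False), (2, 2, False), (5, 2, True),
    ])
    def test_child_criteria(self, n_weekday, n_weekend, ok):
        days = ([make_day(date=f"w{i}") for i in range(n_weekday)]
                + [make_day(date=f"e{i}", weekend=True) for i in range(n_weekend)])
        assert c.child_meets_wear_criteria(days) is ok

    def test_invalid_days_do_not_count(self):
        days = [make_day(date=f"w{i}") for i in range(3)] + \
               [make_day(date="e0", weekend=True, wear=400.0,
                         sed=200, lg=150, walk=20, run=10, mvg=10)]
        assert not c.child_meets_wear_criteria(days)

    def test_mixed_children_rejected(self):
        with pytest.raises(ValueError):
            c.child_meets_wear_criteria([make_day("a"), make_day("b")])


class TestAverageWake:
    def test_energetic_aggregates_walk_run_mvg(self):
        out = average_wake_behaviours([make_day(sed=290, lg=330, walk=20,
                                                run=10, mvg=10, wear=660)])
        assert out == {"sedentary": 290.0, "light_games": 330.0,
                       "energetic": 40.0, "wear": 660.0}

    def test_mean_across_days(self):
        days = [make_day(sed=280.0), make_day(date="d2", sed=300.0)]
        assert average_wake_behaviours(days)["sedentary"] == pytest.approx(290.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_wake_behaviours([])


class TestReallocateNonwear:
    def test_proportional_scaling(self):
        comp = c.reallocate_nonwear(
            {"sedentary": 290.0, "light_games": 330.0, "energetic": 40.0},
            sleep_total_min=690.0)
        assert comp.values.sum() == pytest.approx(1440.0, abs=1e-9)
        assert comp["sleep"] == pytest.approx(690.0)
        assert comp["sedentary"] == pytest.approx(290 * 750 / 660, abs=1e-9)
        assert comp["light_games"] == pytest.approx(375.0, abs=1e-9)
        assert comp["energetic"] == pytest.approx(40 * 750 / 660, abs=1e-9)

    def test_exact_fit_unchanged(self):
        comp = c.reallocate_nonwear(
            {"sedentary": 300.0, "light_games": 400.0, "energetic": 50.0},
            sleep_total_min=690.0)
        assert np.allclose([comp["sedentary"], comp["light_games"],
                            comp["energetic"]], [300, 400, 50], atol=1e-9)

    def test_excess_wear_shrinks(self):
        comp = c.reallocate_nonwear(
            {"sedentary": 500.0, "light_games": 400.0, "energetic": 100.0},
            sleep_total_min=690.0)
        assert comp["sedentary"] < 500.0
        assert comp.values.sum() == pytest.approx(1440.0, abs=1e-9)

    def test_wake_ratios_preserved(self, rng):
        wake = {"sedentary": rng.uniform(100, 400),
                "light_games": rng.uniform(100, 400),
                "energetic": rng.uniform(10, 100)}
        comp = c.reallocate_nonwear(wake, 700.0)
        assert (comp["sedentary"] / comp["light_games"]
                == pytest.approx(wake["sedentary"] / wake["light_games"],
                                 abs=1e-12))

    @pytest.mark.parametrize("sleep", [0.0, 1440.0, 1500.0])
    def test_invalid_sleep_rejected(self, sleep):
        with pytest.raises(Exception):
            c.reallocate_nonwear({"sedentary": 300.0, "light_games": 300.0,
                                  "energetic": 50.0}, sleep)


class TestDisaggregateSedentary:
    @pytest.fixture()
    def base(self):
        return c.close({"sleep": 690.0, "sedentary": 300.0,
                        "light_games": 400.0, "energetic": 50.0})

    def test_proportional_split(self, base):
        out = c.disaggregate_sedentary(base, screen_weekly_min=840.0,
                                       quiet_weekly_min=420.0)
        assert out["screen"] == pytest.approx(200.0)
        assert out["quiet_play"] == pytest.approx(100.0)
        assert out.names == c.BEHAVIOURS_5

    def test_equal_reports_split_evenly(self, base):
        out = c.disaggregate_sedentary(base, 700.0, 700.0)
        assert out["screen"] == pytest.approx(150.0)

    def test_zero_report_replaced_then_split(self, base):
        out = c.disaggregate_sedentary(base, 0.0, 420.0)
        # zero screen becomes 1 min/day against 60 min/day quiet play
        assert out["screen"] == pytest.approx(300.0 * 1.0 / 61.0)

    def test_split_preserves_sedentary_exactly(self, base, rng):
        for _ in range(10):
            s, q = rng.uniform(0, 2000, 2)
            out = c.disaggregate_sedentary(base, s, q)
            assert out["screen"] + out["quiet_play"] == pytest.approx(
                base["sedentary"], abs=1e-12)
            assert out.values.sum() == pytest.approx(1440.0, abs=1e-9)


class TestBuildChildRecords:
    def good_days(self, cid):
        return ([make_day(cid, f"w{i}") for i in range(4)]
                + [make_day(cid, "e0", weekend=True)])

    def test_total_difficulties_is_subscale_sum(self):
        records, counts = c.build_child_records(self.good_days("k1"),
                                                [make_survey("k1")])
        assert counts["included"] == 1
        assert records[0].outcomes["total_difficulties"] == 7.0

    def test_wear_failures_excluded(self):
        days = [make_day("k1", f"w{i}") for i in range(4)]  # no weekend
        _, counts = c.build_child_records(days, [make_survey("k1")])
        assert counts["excluded_wear_criteria"] == 1
        assert counts["included"] == 0

    def test_children_without_accelerometer_excluded(self):
        _, counts = c.build_child_records([], [make_survey("k1")])
        assert counts["excluded_no_accel"] == 1

    def test_missing_report_excluded_only_when_disaggregating(self):
        days = self.good_days("k1")
        surveys = [make_survey("k1", screen=None, quiet=None)]
        recs4, counts4 = c.build_child_records(days, surveys, disaggregate=False)
        recs5, counts5 = c.build_child_records(days, surveys, disaggregate=True)
        assert len(recs4) == 1
        assert len(recs5) == 0
        assert counts5["excluded_missing_sedentary_report"] == 1

    def test_duplicate_survey_rows_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            c.build_child_records(self.good_days("k1"),
                                  [make_survey("k1"), make_survey("k1")])

    def test_compositions_closed_and_consistent(self, small_cohort):
        records, _ = small_cohort
        for r in records[:50]:
            assert r.composition.values.sum() == pytest.approx(1440.0, abs=1e-6)
            assert r.outcomes["total_difficulties"] == pytest.approx(
                sum(r.outcomes[k] for k in
                    ("emotional", "conduct", "hyperactivity", "peer")))


class TestCsvRoundTrip:
    def test_generated_cohort_reads_back(self, tmp_path):
        daily, survey, _ = c.generate_cohort(c.GeneratorConfig(n=40, seed=5))
        daily.to_csv(tmp_path / "daily.csv", index=False)
        survey.to_csv(tmp_path / "survey.csv", index=False)
        days = read_daily_csv(tmp_path / "daily.csv")
        surveys = read_survey_csv(tmp_path / "survey.csv")
        assert len(days) == 40 * 7
        assert len(surveys) == 40
        records, counts = c.build_child_records(days, surveys)
        assert counts["included"] == len(records) > 30
        frame = records_to_frame(records)
        assert {"sleep_min", "sedentary_min", "total_difficulties"} <= set(
            frame.columns)

    def test_schema_mismatch_names_columns(self, tmp_path):
        pd.DataFrame({"child_id": ["a"]}).to_csv(tmp_path / "bad.csv",
                                                 index=False)
        with pytest.raises(ValueError, match="wear_min"):
            read_daily_csv(tmp_path / "bad.csv")
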