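import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from mobifood.mobility_metrics import (
    PeriodScheme,
    ff_visits_food,
    ff_visits_time,
    infer_home,
    night_overlap_seconds,
    observed_periods,
    trips_per_day,
)
from oracles import night_minutes_oracle


def stay_frame(rows):
    """rows: (start, end, is_food, is_ff) ISO strings."""
    return pd.DataFrame(
        {
            "user_id": "u",
            "start": pd.to_datetime([r[0] for r in rows]),
            "end": pd.to_datetime([r[1] for r in rows]),
            "centroid_lat": 34.0,
            "centroid_lon": -118.4,
            "is_food": [r[2] for r in rows],
            "is_ff": [r[3] for r in rows],
        }
    )


class TestObservedPeriods:
    def test_single_morning_stay(self):
        s = stay_frame([("2017-01-02 09:00", "2017-01-02 09:30", False, False)])
        assert observed_periods(s) == {(pd.Timestamp("2017-01-02").date(), 0)}

    def test_three_periods_one_day(self):
        s = stay_frame(
            [
                ("2017-01-02 09:00", "2017-01-02 09:30", False, False),
                ("2017-01-02 12:00", "2017-01-02 12:30", False, False),
                ("2017-01-02 20:00", "2017-01-02 20:30", False, False),
            ]
        )
        assert len(observed_periods(s)) == 3

    def test_empty_stays(self):
        assert observed_periods(stay_frame([])) == set()

    def test_boundaries_are_half_open(self):
        s = stay_frame(
            [
                ("2017-01-02 11:00", "2017-01-02 11:10", False, False),
                ("2017-01-02 16:00", "2017-01-02 16:10", False, False),
            ]
        )
        periods = {p for _, p in observed_periods(s)}
        assert periods == {1, 2}


class TestFFMetrics:
    def test_one_ff_period_of_ten(self):
        rows = [(f"2017-01-{2+d:02d} 09:00", f"2017-01-{2+d:02d} 09:30", False, False) for d in range(9)]
        rows.append(("2017-01-11 12:00", "2017-01-11 12:20", True, True))
        assert ff_visits_time(stay_frame(rows)) == pytest.approx(10.0)

    def test_no_ff_visits_is_zero_percent(self):
        s = stay_frame([("2017-01-02 09:00", "2017-01-02 09:30", True, False)])
        assert ff_visits_time(s) == 0.0

    def test_duplicating_stay_in_ff_period_leaves_rate_unchanged(self):
        rows = [
            ("2017-01-02 09:00", "2017-01-02 09:30", True, True),
            ("2017-01-02 12:00", "2017-01-02 12:30", False, False),
        ]
        base = ff_visits_time(stay_frame(rows))
        dup = ff_visits_time(stay_frame(rows + [("2017-01-02 09:40", "2017-01-02 09:55", True, True)]))
        assert base == dup == 50.0

    @pytest.mark.parametrize("seed", range(5))
    def test_ff_time_equals_direct_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(40):
            day = int(rng.integers(2, 9))
            hour = float(rng.uniform(0, 23.5))
            start = pd.Timestamp(f"2017-01-{day:02d}") + pd.Timedelta(hours=hour)
            is_ff = bool(rng.random() < 0.3)
            rows.append((str(start), str(start + pd.Timedelta(minutes=20)), is_ff, is_ff))
        s = stay_frame(rows).sort_values("start").reset_index(drop=True)
        # direct enumeration over (date, period) pairs
        def period(ts):
            h = ts.hour + ts.minute / 60
            return 0 if h < 11 else (1 if h < 16 else 2)

        slots = {(ts.date(), period(ts)) for ts in s["start"]}
        ff_slots = {(ts.date(), period(ts)) for ts, f in zip(s["start"], s["is_ff"]) if f}
        assert ff_visits_time(s) == pytest.approx(100.0 * len(ff_slots) / len(slots))

    def test_ff_food_ratio_arithmetic(self):
        rows = [("2017-01-02 09:00", "2017-01-02 09:30", True, i < 2) for i in range(20)]
        assert ff_visits_food(stay_frame(rows)) == pytest.approx(10.0)

    def test_ff_food_undefined_without_food_visits(self):
        s = stay_frame([("2017-01-02 09:00", "2017-01-02 09:30", False, False)])
        assert np.isnan(ff_visits_food(s))


class TestTripsPerDay:
    def test_eight_trips_over_two_days(self):
        rows = [(f"2017-01-02 {8+h:02d}:00", f"2017-01-02 {8+h:02d}:30", False, False) for h in range(5)]
        rows += [(f"2017-01-03 {8+h:02d}:00", f"2017-01-03 {8+h:02d}:30", False, False) for h in range(4)]
        assert trips_per_day(stay_frame(rows)) == pytest.approx(4.0)

    def test_single_stay_single_day_is_zero(self):
        assert trips_per_day(stay_frame([("2017-01-02 09:00", "2017-01-02 20:00", False, False)])) == 0.0

    def test_five_stays_one_day(self):
        rows = [(f"2017-01-02 {8+h:02d}:00", f"2017-01-02 {8+h:02d}:30", False, False) for h in range(5)]
        assert trips_per_day(stay_frame(rows)) == pytest.approx(4.0)


NB_GEOMS = [box(-118.5, 33.9, -118.4, 34.0), box(-118.4, 33.9, -118.3, 34.0)]
NB_IDS = ["A", "B"]


def homed_stays(rows):
    """rows: (start, end, lat, lon)."""
    return pd.DataFrame(
        {
            "user_id": "u",
            "start": pd.to_datetime([r[0] for r in rows]),
            "end": pd.to_datetime([r[1] for r in rows]),
            "centroid_lat": [r[2] for r in rows],
            "centroid_lon": [r[3] for r in rows],
        }
    )


class TestInferHome:
    def test_all_night_activity_in_one_neighborhood(self):
        s = homed_stays([("2017-01-02 22:30", "2017-01-03 05:30", 33.95, -118.45)])
        assert infer_home(s, NB_GEOMS, NB_IDS) == "A"

    def test_majority_duration_wins(self):
        s = homed_stays(
            [
                ("2017-01-02 22:00", "2017-01-03 04:00", 33.95, -118.45),  # 6 h in A
                ("2017-01-03 04:30", "2017-01-03 05:30", 33.95, -118.35),  # 1 h in B
            ]
        )
        assert infer_home(s, NB_GEOMS, NB_IDS) == "A"

    def test_daytime_only_user_has_no_home_of_record(self):
        s = homed_stays([("2017-01-02 09:00", "2017-01-02 17:00", 33.95, -118.45)])
        assert infer_home(s, NB_GEOMS, NB_IDS) is None

    def test_centroid_outside_all_polygons_contributes_nothing(self):
        s = homed_stays([("2017-01-02 23:00", "2017-01-03 05:00", 35.0, -118.45)])
        assert infer_home(s, NB_GEOMS, NB_IDS) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_duration_tally(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        t = pd.Timestamp("2017-01-02 00:00")
        for _ in range(30):
            t += pd.Timedelta(minutes=float(rng.uniform(30, 300)))
            dur = pd.Timedelta(minutes=float(rng.uniform(10, 600)))
            lat = float(rng.uniform(33.9, 34.0))
            lon = float(rng.uniform(-118.5, -118.3))
            rows.append((str(t), str(t + dur), lat, lon))
            t += dur
        s = homed_stays(rows)
        got = infer_home(s, NB_GEOMS, NB_IDS)
        # oracle: minute-resolution tally per neighborhood
        tall = {}
        origin = pd.Timestamp("2017-01-01")
        for _, r in s.iterrows():
            nid = "A" if r["centroid_lon"] < -118.4 else "B"
            m0 = (r["start"] - origin).total_seconds() / 60
            m1 = (r["end"] - origin).total_seconds() / 60
            tall[nid] = tall.get(nid, 0) + night_minutes_oracle(m0, m1)
        want = max(tall, key=lambda k: (tall[k], k)) if any(tall.values()) else None
        if want is not None:
            assert got == want

    def test_night_overlap_matches_minute_oracle(self):
        start = pd.Timestamp("2017-01-02 20:00")
        end = pd.Timestamp("2017-01-03 07:00")
        got = night_overlap_seconds(start, end) / 60.0
        origin = pd.Timestamp("2017-01-01")
        want = night_minutes_oracle(
            (start - origin).total_seconds() / 60, (end - origin).total_seconds() / 60
        )
        assert got == pytest.approx(want, abs=1.0)
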