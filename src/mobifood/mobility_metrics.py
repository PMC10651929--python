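"""Per-user mobility measures: FF visits/time, FF visits/food, trips/day, home.

FF visits/time is the percentage of a user's observed daily periods (three per
day: before 11:00, 11:00-16:00, after 16:00 local time) containing at least
one fast-food outlet visit. FF visits/food is the percentage of the user's
food-outlet visits that were to FF outlets. Trips/day is trips (trajectories
between consecutive stays) divided by observation days. The home neighborhood
is the one holding the majority of the user's 22:00-06:00 stay time.

A stay belongs to the daily period of its start time; each attributed stay
counts as one visit. An "observed period" is a (date, period) holding at
least one stay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mobifood.geo import locate_points
from mobifood.stay_detection import count_trips, observation_days

USER_METRIC_COLUMNS = [
    "user_id",
    "home_neighborhood_id",
    "ff_visits_time_pct",
    "ff_visits_food_pct",
    "trips_per_day",
    "n_observed_periods",
    "n_food_visits",
    "n_ff_visits",
    "n_observation_days",
]


@dataclass(frozen=True)
class PeriodScheme:
    """Half-open daily windows [00:00, b0), [b0, b1), [b1, 24:00), hours local."""

    boundaries: tuple[float, float] = (11.0, 16.0)

    def __post_init__(self) -> None:
        b0, b1 = self.boundaries
        if not (0.0 < b0 < b1 < 24.0):
            raise ValueError("period boundaries must satisfy 0 < b0 < b1 < 24")

    def period_of(self, timestamps: pd.Series) -> np.ndarray:
        hours = pd.to_datetime(timestamps)
        frac = hours.dt.hour + hours.dt.minute / 60.0 + hours.dt.second / 3600.0
        return np.searchsorted(np.asarray(self.boundaries), frac.to_numpy(), side="right")


def observed_periods(stays: pd.DataFrame, scheme: PeriodScheme | None = None) -> set:
    """Set of (local date, period index) pairs containing at least one stay start."""
    scheme = scheme or PeriodScheme()
    if len(stays) == 0:
        return set()
    starts = pd.to_datetime(stays["start"])
    return set(zip(starts.dt.date, scheme.period_of(stays["start"])))


def ff_visits_time(attributed_stays: pd.DataFrame, scheme: PeriodScheme | None = None) -> float:
    """% of observed (date, period) slots with >=1 FF-attributed stay; NaN if no slots."""
    scheme = scheme or PeriodScheme()
    all_periods = observed_periods(attributed_stays, scheme)
    if not all_periods:
        return float("nan")
    ff = attributed_stays[attributed_stays["is_ff"].astype(bool)]
    return 100.0 * len(observed_periods(ff, scheme)) / len(all_periods)


def ff_visits_food(attributed_stays: pd.DataFrame) -> float:
    """% of food-outlet visits that were FF; NaN when the user has no food visits."""
    n_food = int(attributed_stays["is_food"].sum())
    if n_food == 0:
        return float("nan")
    return 100.0 * int(attributed_stays["is_ff"].sum()) / n_food


def trips_per_day(stays: pd.DataFrame) -> float:
    """Trips divided by observation days; NaN when no observation days."""
    days = len(observation_days(stays))
    if days == 0:
        return float("nan")
    return count_trips(stays) / days


def night_overlap_seconds(
    start: pd.Timestamp, end: pd.Timestamp, night: tuple[float, float] = (22.0, 6.0)
) -> float:
    """Seconds of [start, end] inside the nightly window (wraps midnight)."""
    n0, n1 = night
    total = 0.0
    day = start.normalize() - pd.Timedelta(days=1)
    stop = end.normalize()
    while day <= stop:
        w0 = day + pd.Timedelta(hours=n0)
        w1 = day + pd.Timedelta(hours=n1 + (24.0 if n1 <= n0 else 0.0))
        lo, hi = max(start, w0), min(end, w1)
        if hi > lo:
            total += (hi - lo).total_seconds()
        day += pd.Timedelta(days=1)
    return total


def infer_home(
    stays: pd.DataFrame,
    neighborhood_geoms,
    neighborhood_ids,
    night: tuple[float, float] = (22.0, 6.0),
):
    """Neighborhood with the largest total 22:00-06:00 stay duration, or None.

    Stays are placed in neighborhoods by point-in-polygon on the stay
    centroid; centroids outside all polygons contribute nothing. Ties break
    by larger stay count in the neighborhood, then by smaller neighborhood id.
    Users with zero nighttime stay time have no home of record (None).
    """
    if len(stays) == 0:
        return None
    idx = locate_points(
        stays["centroid_lat"].to_numpy(float), stays["centroid_lon"].to_numpy(float), neighborhood_geoms
    )
    starts = pd.to_datetime(stays["start"])
    ends = pd.to_datetime(stays["end"])
    duration: dict = {}
    counts: dict = {}
    for i, (s, e) in enumerate(zip(starts, ends)):
        if idx[i] < 0:
            continue
        nid = neighborhood_ids[idx[i]]
        ov = night_overlap_seconds(s, e, night)
        duration[nid] = duration.get(nid, 0.0) + ov
        counts[nid] = counts.get(nid, 0) + 1
    if not duration or max(duration.values()) <= 0.0:
        return None
    return min(duration, key=lambda nid: (-duration[nid], -counts[nid], nid))


def compute_user_metrics(
    attributed_stays: pd.DataFrame,
    neighborhood_geoms,
    neighborhood_ids,
    scheme: PeriodScheme | None = None,
    night: tuple[float, float] = (22.0, 6.0),
) -> pd.DataFrame:
    """Per-user metric table over a multi-user attributed-stay table.

    Users without a home of record, with no observed periods, or with no food
    visits carry NA in the corresponding column; downstream aggregation drops
    them with a warning rather than silently imputing.
    """
    scheme = scheme or PeriodScheme()
    rows = []
    for user, grp in attributed_stays.groupby("user_id", sort=True):
        grp = grp.sort_values("start", kind="stable")
        n_food = int(grp["is_food"].sum())
        n_ff = int(grp["is_ff"].sum())
        rows.append(
            {
                "user_id": user,
                "home_neighborhood_id": infer_home(grp, neighborhood_geoms, neighborhood_ids, night),
                "ff_visits_time_pct": ff_visits_time(grp, scheme),
                "ff_visits_food_pct": ff_visits_food(grp),
                "trips_per_day": trips_per_day(grp),
                "n_observed_periods": len(observed_periods(grp, scheme)),
                "n_food_visits": n_food,
                "n_ff_visits": n_ff,
                "n_observation_days": len(observation_days(grp)),
            }
        )
    return pd.DataFrame(rows, columns=USER_METRIC_COLUMNS)
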