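"""Cluster time-ordered GPS pings into stays; derive trips and observation days.

A *stay* is a dwell event: a maximal run of consecutive pings that all sit
within a roaming distance ``d_roam`` of their coordinate-wise-median centroid.
Clustering is sequential and greedy: the next ping joins the current cluster
iff, after inclusion, the maximum distance from any member to the recomputed
median centroid stays strictly below ``d_roam``; otherwise the cluster is
closed (emitted as a stay iff it has at least ``min_events`` pings and lasts
at least ``min_duration_min``) and the violating ping opens the next cluster.
A closed cluster that fails the thresholds is discarded whole; its pings are
not reassigned. The first and last member ping mark the stay's start and end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mobifood.geo import haversine_m

STAY_COLUMNS = ["user_id", "start", "end", "centroid_lat", "centroid_lon", "n_pings"]

_STAY_DTYPES = {
    "user_id": "object",
    "start": "datetime64[ns]",
    "end": "datetime64[ns]",
    "centroid_lat": "float64",
    "centroid_lon": "float64",
    "n_pings": "int64",
}


def _empty_stays() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _STAY_DTYPES.items()})


@dataclass(frozen=True)
class StayParams:
    """Stay-detection thresholds: 50 m roaming distance, 5 min minimum dwell,
    at least two pings."""

    d_roam_m: float = 50.0
    min_duration_min: float = 5.0
    min_events: int = 2

    def __post_init__(self) -> None:
        if self.d_roam_m <= 0 or self.min_duration_min < 0 or self.min_events <= 0:
            raise ValueError("StayParams thresholds must be positive (duration may be 0)")


def detect_stays(pings: pd.DataFrame, params: StayParams | None = None) -> pd.DataFrame:
    """Cluster one user's time-sorted pings into stays.

    Parameters
    ----------
    pings
        Columns ``user_id``, ``timestamp`` (datetime-like), ``lat``, ``lon``;
        must belong to a single user and be sorted by timestamp.
    params
        Roaming distance / duration / event-count thresholds.

    Returns
    -------
    DataFrame with columns user_id, start, end, centroid_lat, centroid_lon,
    n_pings, chronologically ordered and non-overlapping.
    """
    params = params or StayParams()
    if len(pings) == 0:
        return _empty_stays()
    if pings["user_id"].nunique() > 1:
        raise ValueError("detect_stays operates on a single user's pings")
    ts = pd.to_datetime(pings["timestamp"]).to_numpy()
    if np.any(ts[1:] < ts[:-1]):
        raise ValueError("pings must be sorted by timestamp")
    lat = pings["lat"].to_numpy(dtype=float)
    lon = pings["lon"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("ping coordinates must be finite")
    user = pings["user_id"].iloc[0]

    stays: list[tuple] = []
    start = 0  # index of first ping in the open cluster
    n = len(pings)

    def close(lo: int, hi: int) -> None:
        # emit cluster [lo, hi) if it meets the event and duration floors
        k = hi - lo
        if k < params.min_events:
            return
        dur_min = (ts[hi - 1] - ts[lo]) / np.timedelta64(60, "s")
        if dur_min < params.min_duration_min:
            return
        stays.append(
            (user, ts[lo], ts[hi - 1], float(np.median(lat[lo:hi])), float(np.median(lon[lo:hi])), k)
        )

    for i in range(1, n):
        clat, clon = np.median(lat[start : i + 1]), np.median(lon[start : i + 1])
        if haversine_m(lat[start : i + 1], lon[start : i + 1], clat, clon).max() >= params.d_roam_m:
            close(start, i)
            start = i
    close(start, n)

    if not stays:
        return _empty_stays()
    return pd.DataFrame(stays, columns=STAY_COLUMNS)


def detect_stays_all(pings: pd.DataFrame, params: StayParams | None = None) -> pd.DataFrame:
    """Run :func:`detect_stays` per user on a multi-user ping table.

    Pings are sorted (user, timestamp) first; output order is by user then
    time, so concatenation over users is order-independent.
    """
    params = params or StayParams()
    if len(pings) == 0:
        return _empty_stays()
    out = [
        detect_stays(grp.sort_values("timestamp", kind="stable"), params)
        for _, grp in pings.groupby("user_id", sort=True)
    ]
    return pd.concat(out, ignore_index=True)


def count_trips(stays: pd.DataFrame) -> int:
    """Number of trips (trajectories between consecutive stays): max(0, n_stays - 1)."""
    return max(0, len(stays) - 1)


def observation_days(stays: pd.DataFrame, timestamp_col: str = "start") -> set:
    """Distinct local calendar dates with at least one stay (or ping)."""
    if len(stays) == 0:
        return set()
    return set(pd.to_datetime(stays[timestamp_col]).dt.date)
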