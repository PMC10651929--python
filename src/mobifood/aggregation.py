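"""Neighborhood aggregation of user metrics and linkage to survey respondents.

User-level FF measures are averaged over users whose inferred home lies in a
neighborhood, then rescaled so that one unit of the scaled variable equals 10
percentage points (percentage / 10, mapping 0-100% onto 0-10). Trips/day is
already on a 0-10-compatible scale and is left unscaled by default; a min-max
[0, 10] alternative is available via ``trips_scaling="minmax"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

NEIGHBORHOOD_METRIC_COLUMNS = [
    "neighborhood_id",
    "n_users",
    "mean_ff_time_pct",
    "mean_ff_food_pct",
    "mean_trips_day",
    "var_ff_time",
    "var_ff_food",
    "scaled_ff_time",
    "scaled_ff_food",
    "scaled_trips_day",
]

CONTEXTUAL_COLUMNS = ["scaled_ff_time", "scaled_ff_food", "scaled_trips_day"]


def aggregate_by_neighborhood(user_metrics: pd.DataFrame, min_users: int = 5) -> pd.DataFrame:
    """Mean and population variance of user metrics per home neighborhood.

    Users lacking a home neighborhood or a defined metric (NaN ff_visits_food
    from zero food visits, say) are dropped from the affected averages.
    Neighborhoods with fewer than ``min_users`` contributing users are dropped
    with a warning: small cells are both noisy and privacy-hostile.
    """
    if len(user_metrics) == 0:
        return pd.DataFrame(columns=NEIGHBORHOOD_METRIC_COLUMNS)
    um = user_metrics.dropna(subset=["home_neighborhood_id"])
    rows = []
    for nid, grp in um.groupby("home_neighborhood_id", sort=True):
        if len(grp) < min_users:
            warnings.warn(
                f"neighborhood {nid!r} dropped: {len(grp)} users < min_users={min_users}",
                stacklevel=2,
            )
            continue
        ff_time = grp["ff_visits_time_pct"].dropna()
        ff_food = grp["ff_visits_food_pct"].dropna()
        rows.append(
            {
                "neighborhood_id": nid,
                "n_users": len(grp),
                "mean_ff_time_pct": float(ff_time.mean()),
                "mean_ff_food_pct": float(ff_food.mean()),
                "mean_trips_day": float(grp["trips_per_day"].dropna().mean()),
                "var_ff_time": float(np.var(ff_time)),  # population variance (ddof 0)
                "var_ff_food": float(np.var(ff_food)),
            }
        )
    return rescale(pd.DataFrame(rows))


def rescale(neighborhood_metrics: pd.DataFrame, trips_scaling: str = "identity") -> pd.DataFrame:
    """Add 0-10 scaled exposure columns: percentage / 10; trips/day per ``trips_scaling``."""
    out = neighborhood_metrics.copy()
    if len(out) == 0:
        return pd.DataFrame(columns=NEIGHBORHOOD_METRIC_COLUMNS)
    out["scaled_ff_time"] = out["mean_ff_time_pct"] / 10.0
    out["scaled_ff_food"] = out["mean_ff_food_pct"] / 10.0
    if trips_scaling == "identity":
        out["scaled_trips_day"] = out["mean_trips_day"]
    elif trips_scaling == "minmax":
        lo, hi = out["mean_trips_day"].min(), out["mean_trips_day"].max()
        rng = hi - lo
        out["scaled_trips_day"] = 0.0 if rng == 0 else 10.0 * (out["mean_trips_day"] - lo) / rng
    else:
        raise ValueError(f"unknown trips_scaling {trips_scaling!r}")
    return out[[c for c in NEIGHBORHOOD_METRIC_COLUMNS if c in out.columns]]


def link_to_respondents(
    respondents: pd.DataFrame, neighborhood_metrics: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Attach each respondent's residential-neighborhood contextual variables.

    Returns (analytic table, number of respondents flagged and excluded
    because their neighborhood is absent from the metrics table — e.g.
    dropped below min_users). Flagged counts are also warned.
    """
    ctx = neighborhood_metrics.set_index("neighborhood_id")[CONTEXTUAL_COLUMNS]
    merged = respondents.merge(
        ctx, how="left", left_on="neighborhood_id", right_index=True, validate="many_to_one"
    )
    has_nbhd = merged["neighborhood_id"].notna()
    unmatched = int((has_nbhd & merged["scaled_ff_time"].isna()).sum())
    if unmatched:
        warnings.warn(f"{unmatched} respondents in neighborhoods without metrics; excluded", stacklevel=2)
    keep = ~(has_nbhd & merged["scaled_ff_time"].isna())
    return merged[keep].reset_index(drop=True), unmatched
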