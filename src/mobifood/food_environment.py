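"""POI table maintenance: food / fast-food classification and stay attribution.

Food outlets are any POI whose category belongs to a configured food-category
set; fast-food (FF) outlets are the subset whose normalized name matches a
validated chain-brand list (e.g. McDonald's, Taco Bell, Pizza Hut). Each stay
is attributed to the haversine-nearest POI within a maximum distance d_max
(200 m by default), measured from the stay centroid to the POI point.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from mobifood.geo import haversine_m

_NORM_RE = re.compile(r"[^a-z0-9 ]+")


@dataclass(frozen=True)
class AttributionParams:
    d_max_m: float = 200.0

    def __post_init__(self) -> None:
        if self.d_max_m <= 0:
            raise ValueError("d_max_m must be positive")


def normalize_name(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace: "McDonald's #12" -> "mcdonalds 12"."""
    return " ".join(_NORM_RE.sub(" ", str(name).lower().replace("'", "")).split())


def _brand_matches(norm_name: str, norm_brands: list[str]) -> bool:
    # token-prefix match: the brand's tokens must open the outlet name
    toks = norm_name.split()
    for brand in norm_brands:
        btoks = brand.split()
        if toks[: len(btoks)] == btoks:
            return True
    return False


def classify_food_outlets(
    poi: pd.DataFrame, food_categories: Iterable[str], ff_brands: Iterable[str]
) -> pd.DataFrame:
    """Flag food outlets by category and FF outlets by brand-name match.

    ``is_food`` iff category is in ``food_categories``; ``is_ff`` iff is_food
    and the normalized name starts with a normalized brand ("TACO BELL -
    Downtown" matches "Taco Bell"). Idempotent and row-order independent.
    """
    food_set = set(food_categories)
    norm_brands = [normalize_name(b) for b in ff_brands if normalize_name(b)]
    if not norm_brands:
        warnings.warn("empty fast-food brand list: no POI will be flagged is_ff", stacklevel=2)
    out = poi.copy()
    out["is_food"] = out["category"].isin(food_set)
    names = out["name"].map(normalize_name)
    out["is_ff"] = out["is_food"] & names.map(lambda s: _brand_matches(s, norm_brands))
    return out


def attribute_stays(
    stays: pd.DataFrame, poi: pd.DataFrame, params: AttributionParams | None = None
) -> pd.DataFrame:
    """Attach to each stay the nearest POI within d_max of its centroid.

    Adds columns poi_id (NA when no POI within d_max), dist_m, is_food, is_ff.
    Ties at identical distance break to the smallest poi_id; a POI exactly at
    d_max does not qualify (strict "<").
    """
    params = params or AttributionParams()
    out = stays.copy()
    if len(poi) == 0 or len(stays) == 0:
        out["poi_id"] = pd.array([pd.NA] * len(out))
        out["dist_m"] = np.nan
        out["is_food"] = False
        out["is_ff"] = False
        return out
    p = poi.sort_values("poi_id", kind="stable").reset_index(drop=True)
    plat = p["lat"].to_numpy(dtype=float)
    plon = p["lon"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(plat)) and np.all(np.isfinite(plon))):
        raise ValueError("POI coordinates must be finite")
    slat = out["centroid_lat"].to_numpy(dtype=float)
    slon = out["centroid_lon"].to_numpy(dtype=float)
    # all-pairs in blocks to bound memory; argmin picks the first (smallest
    # poi_id) among equidistant POIs because p is sorted by poi_id
    nearest = np.empty(len(out), dtype=int)
    best = np.empty(len(out), dtype=float)
    step = max(1, 20_000_000 // max(1, len(p)))
    for lo in range(0, len(out), step):
        hi = min(lo + step, len(out))
        d = haversine_m(slat[lo:hi, None], slon[lo:hi, None], plat[None, :], plon[None, :])
        nearest[lo:hi] = np.argmin(d, axis=1)
        best[lo:hi] = d[np.arange(hi - lo), nearest[lo:hi]]
    within = best < params.d_max_m
    out["poi_id"] = pd.array([p["poi_id"].iloc[j] if w else pd.NA for j, w in zip(nearest, within)])
    out["dist_m"] = np.where(within, best, np.nan)
    out["is_food"] = within & p["is_food"].to_numpy()[nearest]
    out["is_ff"] = within & p["is_ff"].to_numpy()[nearest]
    return out


def food_visit_share(attributed_stays: pd.DataFrame) -> float:
    """Percentage of all stays attributed to food outlets."""
    if len(attributed_stays) == 0:
        raise ValueError("food_visit_share undefined for zero stays")
    return food_visit_share_from_counts(int(attributed_stays["is_food"].sum()), len(attributed_stays))


def food_visit_share_from_counts(n_food_stays: int, n_stays: int) -> float:
    """Food-stay share as a percentage from raw counts."""
    if n_stays <= 0:
        raise ValueError("food_visit_share undefined for zero stays")
    return 100.0 * n_food_stays / n_stays
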