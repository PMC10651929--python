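"""Synthetic study world with planted parameters.

Generates a grid of neighborhoods subdivided into census-like tracts, a POI
table with labelled food and fast-food outlets, per-user geolocation ping
streams, a health-survey respondent table, and two tract demographic tables.
Every quantity the downstream pipeline estimates has a planted ground truth,
so stay detection, attribution, aggregation and the regression models can be
validated by parameter recovery instead of restricted real data.

What the generator emulates: irregular 5-15 min ping sampling; isotropic GPS
noise with a configurable median radial error (21 m by default); whole
(day, period) observation blocks dropped at random, as when a phone is out of
service; daily routines of home, work and food-outlet stays in which the
choice of a fast-food versus other food outlet follows a per-neighborhood
propensity; survey outcomes (four-level FF intake, obesity, diabetes) drawn
from multinomial-logit / logistic models on the neighborhood's true scaled
exposure with planted log-odds; tract demographics stable between two years
except for designated outlier tracts.

Geometry is a local planar grid anchored at a fixed lat/lon; distances use
the same haversine as the pipeline, so generator and pipeline agree. Home and
work anchors are placed at least a buffer distance away from any POI, keeping
residential dwells distinct from commercial visits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from mobifood.geo import write_geojson

ORIGIN_LAT = 34.0
ORIGIN_LON = -118.4
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON = 111.320 * math.cos(math.radians(ORIGIN_LAT))
START_DATE = pd.Timestamp("2017-01-02")

FF_BRANDS = [
    "McDonald's",
    "Taco Bell",
    "Pizza Hut",
    "Burger King",
    "KFC",
    "Subway",
    "Jack in the Box",
    "Wendy's",
]
DEFAULT_FOOD_CATEGORIES = ["Restaurant", "Fast Food Restaurant", "Grocery Store"]
_NONFOOD_CATEGORIES = ["Park", "Retail Store", "Gym", "Bank"]

# median of a Rayleigh(sigma) radial error is sigma * sqrt(2 ln 2)
_RAYLEIGH_MEDIAN = math.sqrt(2.0 * math.log(2.0))

_DEMOGRAPHICS = {
    "age_group": (
        ["18-24", "25-29", "30-39", "40-49", "50-59", "60-64", "65+"],
        [0.086, 0.063, 0.161, 0.195, 0.205, 0.085, 0.205],
    ),
    "gender": (["female", "male"], [0.588, 0.412]),
    "race_ethnicity": (
        ["white", "hispanic_latino", "black_african_american", "asian", "multiracial_other"],
        [0.414, 0.376, 0.107, 0.079, 0.024],
    ),
    "education": (
        ["less_than_high_school", "high_school", "some_college", "college_or_postgraduate"],
        [0.173, 0.177, 0.259, 0.391],
    ),
    "income": (["low", "high"], [0.389, 0.611]),
}


@dataclass(frozen=True)
class WorldConfig:
    """Study-condition knobs for the synthetic world.

    Percentage-exposure effects are planted on the *scaled* exposure
    (true FF share of food visits x 10), matching the pipeline's 0-10
    rescaled contextual variables.
    """

    n_neighborhoods: int = 12
    grid_cell_km: float = 2.0
    n_tracts_per_neighborhood: int = 4
    n_poi_per_neighborhood: int = 30
    ff_fraction_range: tuple[float, float] = (0.08, 0.25)
    n_users: int = 240
    n_respondents: int = 3000
    days: int = 7
    ping_interval_min_range: tuple[float, float] = (5.0, 15.0)
    ping_accuracy_median_m: float = 21.0
    period_dropout_prob: float = 0.2
    seed: int = 0
    # world composition
    food_poi_fraction: float = 0.6
    ff_propensity_range: tuple[float, float] = (0.05, 0.35)
    anchor_poi_buffer_m: float = 250.0
    # daily behavior
    p_food_visit_per_period: float = 0.4
    p_work_day: float = 0.7
    # planted survey model (log-odds per scaled-exposure unit; study-scale ORs)
    intake_log_or: tuple[float, float, float] = (
        math.log(1.13),
        math.log(1.26),
        math.log(1.35),
    )
    intake_intercepts: tuple[float, float, float] = (-0.133, 0.0, 0.178)
    obesity_log_or: float = math.log(1.16)
    obesity_intercept: float = -1.40
    diabetes_log_or: float = math.log(1.15)
    diabetes_intercept: float = -2.37
    covariate_log_or: dict = field(default_factory=dict)  # {outcome: {column: {category: log-odds}}}
    trips_log_or: float = 0.0
    # survey missingness / exclusions
    missing_residence_frac: float = 0.0
    rural_frac: float = 0.0
    missing_value_frac: float = 0.0
    # tract demographic change
    n_outlier_tracts: int = 2
    tract_outlier_shift: float = 30.0
    tract_change_sd: tuple[float, float, float] = (8.0, 5.0, 7.5)

    def __post_init__(self) -> None:
        counts = (
            self.n_neighborhoods,
            self.n_tracts_per_neighborhood,
            self.n_poi_per_neighborhood,
            self.n_users,
            self.n_respondents,
            self.days,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("counts must all be positive")
        if self.n_neighborhoods < 2:
            raise ValueError("aggregation needs at least 2 neighborhoods")
        for pr in (self.period_dropout_prob, self.missing_residence_frac, self.rural_frac, self.missing_value_frac):
            if not 0.0 <= pr <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for rng_pair in (self.ff_fraction_range, self.ff_propensity_range):
            lo, hi = rng_pair
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("fraction ranges must be ordered within [0, 1]")
        lo, hi = self.ping_interval_min_range
        if not (0.0 < lo <= hi):
            raise ValueError("ping interval range must be positive and ordered")


@dataclass
class PlantedTruth:
    """Ground truth for parameter-recovery tests."""

    neighborhood_ff_propensity: dict[str, float]
    intake_coefficients: dict
    disease_coefficients: dict
    outlier_tracts: list[str]
    seed: int | None = None

    def scaled_exposure(self, neighborhood_id: str) -> float:
        """True scaled FF visits/food exposure: propensity x 100% / 10."""
        return 10.0 * self.neighborhood_ff_propensity[neighborhood_id]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class World:
    config: WorldConfig
    neighborhood_ids: list[str]
    neighborhood_geoms: list
    tracts: pd.DataFrame  # tract_id, neighborhood_id
    tract_geoms: list
    poi: pd.DataFrame
    truth: PlantedTruth

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_geojson(
            out / "neighborhoods.geojson",
            self.neighborhood_geoms,
            [{"neighborhood_id": nid} for nid in self.neighborhood_ids],
        )
        write_geojson(
            out / "tracts.geojson",
            self.tract_geoms,
            self.tracts.to_dict("records"),
        )
        self.poi.to_csv(out / "poi.csv", index=False)
        self.truth.to_json(out / "truth.json")


def _to_lat(y_km: float) -> float:
    return ORIGIN_LAT + y_km / KM_PER_DEG_LAT


def _to_lon(x_km: float) -> float:
    return ORIGIN_LON + x_km / KM_PER_DEG_LON


def _grid_shape(n: int) -> tuple[int, int]:
    # most-square factor pair (rows, cols) so the cells tile a rectangle
    best = (1, n)
    for r in range(1, int(math.sqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def make_world(config: WorldConfig) -> World:
    """Build neighborhoods, tracts, the POI table and the planted truth.

    Deterministic given ``config.seed``: the same config yields byte-identical
    outputs. Fast-food outlets are a labelled subset of food outlets whose
    per-neighborhood share is drawn from ``ff_fraction_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows, cols = _grid_shape(config.n_neighborhoods)
    cell = config.grid_cell_km

    neighborhood_ids, nbhd_geoms, tract_rows, tract_geoms = [], [], [], []
    for i in range(config.n_neighborhoods):
        r, c = divmod(i, cols)
        x0, y0 = c * cell, r * cell
        nid = f"N{i:02d}"
        neighborhood_ids.append(nid)
        nbhd_geoms.append(box(_to_lon(x0), _to_lat(y0), _to_lon(x0 + cell), _to_lat(y0 + cell)))
        nt = config.n_tracts_per_neighborhood
        for t in range(nt):  # vertical strips
            tx0 = x0 + t * cell / nt
            tract_rows.append({"tract_id": f"{nid}-T{t}", "neighborhood_id": nid})
            tract_geoms.append(
                box(_to_lon(tx0), _to_lat(y0), _to_lon(tx0 + cell / nt), _to_lat(y0 + cell))
            )

    # per-neighborhood FF propensity: evenly spaced (monotone in id) so the
    # planted ordering is recoverable without ties
    lo, hi = config.ff_propensity_range
    props = np.linspace(lo, hi, config.n_neighborhoods)

    poi_rows = []
    k = 0
    for i, nid in enumerate(neighborhood_ids):
        r, c = divmod(i, cols)
        x0, y0 = c * cell, r * cell
        n_poi = config.n_poi_per_neighborhood
        n_food = int(round(config.food_poi_fraction * n_poi))
        ff_frac = rng.uniform(*config.ff_fraction_range)
        n_ff = int(round(ff_frac * n_food))
        xs = x0 + cell * rng.uniform(0.02, 0.98, n_poi)
        ys = y0 + cell * rng.uniform(0.02, 0.98, n_poi)
        for j in range(n_poi):
            if j < n_ff:
                brand = FF_BRANDS[rng.integers(len(FF_BRANDS))]
                name, category = f"{brand} #{k}", "Fast Food Restaurant"
            elif j < n_food:
                name = f"{'Cafe' if j % 2 else 'Market'} {k}"
                category = "Restaurant" if j % 2 else "Grocery Store"
            else:
                category = _NONFOOD_CATEGORIES[j % len(_NONFOOD_CATEGORIES)]
                name = f"{category} {k}"
            poi_rows.append(
                {
                    "poi_id": f"P{k:05d}",
                    "name": name,
                    "lat": _to_lat(ys[j]),
                    "lon": _to_lon(xs[j]),
                    "category": category,
                    "is_food": j < n_food,
                    "is_ff": j < n_ff,
                    "neighborhood_id": nid,
                }
            )
            k += 1
    poi = pd.DataFrame(poi_rows)

    tracts = pd.DataFrame(tract_rows)
    n_out = min(config.n_outlier_tracts, len(tracts))
    outliers = sorted(rng.choice(tracts["tract_id"].to_numpy(), size=n_out, replace=False).tolist())

    truth = PlantedTruth(
        neighborhood_ff_propensity={nid: float(p) for nid, p in zip(neighborhood_ids, props)},
        intake_coefficients={
            "categories": ["infrequent", "moderate", "frequent"],
            "intercepts": list(config.intake_intercepts),
            "log_or_per_scaled_unit": list(config.intake_log_or),
        },
        disease_coefficients={
            "obesity": {
                "intercept": config.obesity_intercept,
                "log_or_per_scaled_unit": config.obesity_log_or,
                "covariates": config.covariate_log_or.get("obesity", {}),
                "trips_log_or": config.trips_log_or,
            },
            "diabetes": {
                "intercept": config.diabetes_intercept,
                "log_or_per_scaled_unit": config.diabetes_log_or,
                "covariates": config.covariate_log_or.get("diabetes", {}),
                "trips_log_or": config.trips_log_or,
            },
        },
        outlier_tracts=outliers,
        seed=config.seed,
    )
    return World(config, neighborhood_ids, nbhd_geoms, tracts, tract_geoms, poi, truth)


def _sample_anchor(rng, x0, y0, cell, poi_xy_km, buffer_km) -> tuple[float, float]:
    """Uniform point in the cell at least ``buffer_km`` from every POI."""
    best, best_d = None, -1.0
    for _ in range(200):
        x = x0 + cell * rng.uniform(0.02, 0.98)
        y = y0 + cell * rng.uniform(0.02, 0.98)
        d = np.sqrt(((poi_xy_km - [x, y]) ** 2).sum(axis=1)).min() if len(poi_xy_km) else np.inf
        if d >= buffer_km:
            return x, y
        if d > best_d:
            best, best_d = (x, y), d
    return best


def simulate_users(world: World, config: WorldConfig | None = None):
    """Simulate ping streams for all users.

    Each user lives at a home anchor in one neighborhood (users spread evenly
    over neighborhoods) and follows a daily routine of home, optional work,
    and per-period food-outlet stays; the FF-vs-other choice of each food
    visit is Bernoulli with the home neighborhood's planted propensity. Pings
    inside each stay arrive at irregular intervals and are jittered with
    isotropic Gaussian noise whose median radial error equals the configured
    accuracy. Whole (day, period) blocks are dropped with
    ``period_dropout_prob``.

    Returns
    -------
    (pings, users, visits):
        pings — user_id, timestamp (ISO local), lat, lon, accuracy_m;
        users — per-user home anchor and true home neighborhood;
        visits — the generator's own log of food-outlet visits (ground truth).
    """
    config = config or world.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows, cols = _grid_shape(config.n_neighborhoods)
    cell = config.grid_cell_km
    sigma_m = config.ping_accuracy_median_m / _RAYLEIGH_MEDIAN
    poi_xy_km = np.column_stack(
        [
            (world.poi["lon"].to_numpy() - ORIGIN_LON) * KM_PER_DEG_LON,
            (world.poi["lat"].to_numpy() - ORIGIN_LAT) * KM_PER_DEG_LAT,
        ]
    )
    food_poi = world.poi[world.poi["is_food"]]
    ff_ids = food_poi.index[food_poi["is_ff"]].to_numpy()
    nonff_ids = food_poi.index[~food_poi["is_ff"]].to_numpy()

    lo_int, hi_int = config.ping_interval_min_range
    drop = rng.random((config.n_users, config.days, 3)) < config.period_dropout_prob

    # fixed within-day slots (hours); food slots fall in periods 0 / 1 / 2
    food_slots = [(8.0, 8.0 + 25 / 60), (12.0, 12.5), (17.5, 18.0)]

    ping_rows, user_rows, visit_rows = [], [], []
    for u in range(config.n_users):
        uid = f"U{u:04d}"
        nb = u % config.n_neighborhoods
        nid = world.neighborhood_ids[nb]
        prop = world.truth.neighborhood_ff_propensity[nid]
        r, c = divmod(nb, cols)
        hx, hy = _sample_anchor(rng, c * cell, r * cell, cell, poi_xy_km, config.anchor_poi_buffer_m / 1000.0)
        wc = rng.integers(config.n_neighborhoods)
        wr, wcc = divmod(int(wc), cols)
        wx, wy = _sample_anchor(rng, wcc * cell, wr * cell, cell, poi_xy_km, config.anchor_poi_buffer_m / 1000.0)
        home = (_to_lat(hy), _to_lon(hx))
        work = (_to_lat(wy), _to_lon(wx))
        user_rows.append({"user_id": uid, "home_neighborhood_id": nid, "home_lat": home[0], "home_lon": home[1]})

        for day in range(config.days):
            day0 = START_DATE + pd.Timedelta(days=day)
            workday = rng.random() < config.p_work_day
            intervals: list[tuple[float, float, float, float]] = [(0.0, 7.0 + 40 / 60, *home)]
            for p, (s, e) in enumerate(food_slots):
                if rng.random() < config.p_food_visit_per_period:
                    is_ff = (rng.random() < prop) and len(ff_ids) > 0
                    pool = ff_ids if is_ff else nonff_ids
                    if len(pool) == 0:
                        continue
                    pidx = pool[rng.integers(len(pool))]
                    prow = world.poi.loc[pidx]
                    intervals.append((s, e, prow["lat"], prow["lon"]))
                    visit_rows.append(
                        {"user_id": uid, "day": day, "period": p, "poi_id": prow["poi_id"], "is_ff": bool(is_ff)}
                    )
            if workday:
                intervals.append((8.75, 11.75, *work))
                intervals.append((12.85, 16.0 + 40 / 60, *work))
            intervals.append((19.0, 23.99, *home))
            intervals.sort()

            for s, e, plat, plon in intervals:
                t = s
                while t <= e:
                    period = 0 if t < 11.0 else (1 if t < 16.0 else 2)
                    dx, dy = rng.normal(0.0, sigma_m, 2)
                    acc_draw = rng.normal(0.0, 0.3)
                    if not drop[u, day, period]:
                        acc = (
                            float(config.ping_accuracy_median_m * np.exp(acc_draw))
                            if config.ping_accuracy_median_m > 0
                            else 0.0
                        )
                        ping_rows.append(
                            (
                                uid,
                                day0 + pd.Timedelta(hours=t),
                                plat + dy / 1000.0 / KM_PER_DEG_LAT,
                                plon + dx / 1000.0 / KM_PER_DEG_LON,
                                acc,
                            )
                        )
                    t += rng.uniform(lo_int, hi_int) / 60.0

    pings = pd.DataFrame(ping_rows, columns=["user_id", "timestamp", "lat", "lon", "accuracy_m"])
    pings["timestamp"] = pd.to_datetime(pings["timestamp"]).dt.round("s")
    users = pd.DataFrame(user_rows)
    visits = pd.DataFrame(visit_rows, columns=["user_id", "day", "period", "poi_id", "is_ff"])
    return pings, users, visits


def simulate_survey(world: World, truth: PlantedTruth | None = None, config: WorldConfig | None = None) -> pd.DataFrame:
    """Simulate health-survey respondents with outcomes driven by the truth.

    Each respondent gets a residential tract (uniform over tracts, hence a
    neighborhood), categorical demographics drawn from fixed urban-survey
    marginals, a four-level FF intake from a multinomial logit on the
    neighborhood's true scaled exposure, and obesity/diabetes from logistic
    models with the planted log-odds. Missingness and rural flags exercise
    the exclusion rules.
    """
    config = config or world.config
    truth = truth or world.truth
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = config.n_respondents

    tract_ids = world.tracts["tract_id"].to_numpy()
    tract_nbhd = world.tracts.set_index("tract_id")["neighborhood_id"]
    t_idx = rng.integers(len(tract_ids), size=n)
    tract = tract_ids[t_idx]
    nbhd = tract_nbhd.loc[tract].to_numpy()
    x = np.array([truth.scaled_exposure(nid) for nid in nbhd])

    df = pd.DataFrame({"id": [f"R{i:05d}" for i in range(n)], "tract_id": tract, "neighborhood_id": nbhd})
    for col, (cats, probs) in _DEMOGRAPHICS.items():
        df[col] = rng.choice(cats, size=n, p=np.asarray(probs) / np.sum(probs))

    ic = truth.intake_coefficients
    logits = np.zeros((n, 4))
    for j, (a, b) in enumerate(zip(ic["intercepts"], ic["log_or_per_scaled_unit"]), start=1):
        logits[:, j] = a + b * x
    pmat = np.exp(logits - logits.max(axis=1, keepdims=True))
    pmat /= pmat.sum(axis=1, keepdims=True)
    cum = np.cumsum(pmat, axis=1)
    draw = rng.random(n)
    codes = (draw[:, None] > cum).sum(axis=1)
    from mobifood.epi_models import INTAKE_LEVELS

    df["ff_intake"] = np.asarray(INTAKE_LEVELS, dtype=object)[codes]

    for outcome in ("obesity", "diabetes"):
        dc = truth.disease_coefficients[outcome]
        eta = dc["intercept"] + dc["log_or_per_scaled_unit"] * x
        for col, effects in dc.get("covariates", {}).items():
            eta = eta + df[col].map(lambda c: effects.get(c, 0.0)).to_numpy(float)
        df[outcome] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)

    df["rural"] = rng.random(n) < config.rural_frac
    miss_res = rng.random(n) < config.missing_residence_frac
    df.loc[miss_res, ["tract_id", "neighborhood_id"]] = pd.NA
    miss_val = rng.random(n) < config.missing_value_frac
    study_cols = list(_DEMOGRAPHICS) + ["ff_intake", "obesity", "diabetes"]
    which = rng.integers(len(study_cols), size=n)
    for i in np.flatnonzero(miss_val):
        df.loc[i, study_cols[which[i]]] = pd.NA
    return df


def simulate_tract_demographics(world: World, truth: PlantedTruth | None = None, config: WorldConfig | None = None):
    """Two tract demographic tables (year A, year B) with planted outliers.

    Three percentage variables per tract: % of population above 200% FPL,
    % Black or African American alone, % Hispanic or Latino. Non-outlier
    tracts change by N(0, sd) per variable; outlier tracts additionally
    shift by ``tract_outlier_shift`` points. Percentages are clipped to
    [0, 100]. The default change sds put the 95th percentile of |change|
    near the 16 / 10 / 15-point stability thresholds.
    """
    config = config or world.config
    truth = truth or world.truth
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    tracts = world.tracts["tract_id"]
    n = len(tracts)
    year_a = pd.DataFrame(
        {
            "tract_id": tracts,
            "pct_above_200fpl": rng.uniform(40.0, 90.0, n),
            "pct_black": rng.uniform(2.0, 25.0, n),
            "pct_hispanic": rng.uniform(10.0, 70.0, n),
        }
    )
    year_b = year_a.copy()
    is_out = tracts.isin(truth.outlier_tracts).to_numpy()
    for col, sd in zip(["pct_above_200fpl", "pct_black", "pct_hispanic"], config.tract_change_sd):
        delta = rng.normal(0.0, sd, n)
        delta[is_out] += config.tract_outlier_shift
        year_b[col] = np.clip(year_a[col] + delta, 0.0, 100.0)
    year_a[["pct_above_200fpl", "pct_black", "pct_hispanic"]] = year_a[
        ["pct_above_200fpl", "pct_black", "pct_hispanic"]
    ].clip(0.0, 100.0)
    return year_a, year_b
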