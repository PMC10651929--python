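"""Temporal-stability sensitivity analysis and the general-mobility check.

Census-tract demographic change between two survey years is summarized per
tract for three percentage variables (% above 200% of the Federal Poverty
Limit, % Black or African American alone, % Hispanic or Latino). Tracts with
outlying change are flagged by two methods — Tukey fences (1.5 x IQR beyond
the quartiles) and two sample standard deviations from the mean — taking the
union over the three variables. The primary regression models are then refit
without respondents living in outlier tracts, and per-term odds-ratio
percentage changes above 10% are flagged as meaningful. A separate check
refits the disease models with trips/day added as a covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mobifood.epi_models import (
    INTAKE_LEVELS,
    ModelFitError,
    RegressionResult,
    fit_binary,
    fit_multinomial,
)

CHANGE_VARIABLES = {"delta_fpl": "pct_above_200fpl", "delta_black": "pct_black", "delta_hispanic": "pct_hispanic"}

PRIMARY_EXPOSURES = ("scaled_ff_time", "scaled_ff_food")


def tract_changes(year_a: pd.DataFrame, year_b: pd.DataFrame) -> pd.DataFrame:
    """Per-tract (year B - year A) differences of the three percentage variables.

    Tracts present in only one year are excluded (and counted in the
    ``n_dropped`` attribute); fully disjoint id sets are an error.
    """
    common = pd.Index(sorted(set(year_a["tract_id"]) & set(year_b["tract_id"])))
    if len(common) == 0:
        raise ValueError("tract id sets are disjoint: cannot compute changes")
    a = year_a.set_index("tract_id").loc[common]
    b = year_b.set_index("tract_id").loc[common]
    out = pd.DataFrame({"tract_id": common})
    for delta_col, src in CHANGE_VARIABLES.items():
        out[delta_col] = (b[src].to_numpy(float) - a[src].to_numpy(float))
    out.attrs["n_dropped"] = len(set(year_a["tract_id"]) ^ set(year_b["tract_id"]))
    return out


def flag_outliers(changes: pd.DataFrame, method: int) -> set:
    """Union over the three change variables of per-variable outlier tracts.

    Method 1 (Tukey): x > Q3 + 1.5 IQR or x < Q1 - 1.5 IQR, quartiles by
    linear interpolation. Method 2: |x - mean| > 2 sd (sample sd, ddof 1).
    Strict inequalities, so a constant vector yields no outliers.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 (Tukey) or 2 (2-SD)")
    flagged: set = set()
    ids = changes["tract_id"].to_numpy()
    for col in CHANGE_VARIABLES:
        x = changes[col].to_numpy(float)
        if method == 1:
            q1, q3 = np.quantile(x, [0.25, 0.75])
            iqr = q3 - q1
            mask = (x > q3 + 1.5 * iqr) | (x < q1 - 1.5 * iqr)
        else:
            mu = x.mean()
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
            mask = np.abs(x - mu) > 2.0 * sd
        flagged.update(ids[mask])
    return flagged


def stability_quantile(changes: pd.DataFrame, variable: str) -> float:
    """z such that P(|delta| < z) = 0.95: the empirical 95th percentile of
    absolute change, linear interpolation between order statistics."""
    x = np.abs(changes[variable].to_numpy(float))
    if len(x) == 0:
        raise ValueError("empty change vector")
    return float(np.quantile(x, 0.95))


def fit_primary_models(analytic: pd.DataFrame) -> dict[str, RegressionResult]:
    """The six primary models: per exposure, unadjusted multinomial intake and
    adjusted obesity / diabetes logits."""
    out: dict[str, RegressionResult] = {}
    for exposure in PRIMARY_EXPOSURES:
        out[f"intake~{exposure}"] = fit_multinomial(analytic, exposure, adjusted=False)
        for outcome in ("obesity", "diabetes"):
            out[f"{outcome}~{exposure}"] = fit_binary(analytic, outcome, exposure, adjusted=True)
    return out


def _or_change_rows(name: str, method: str, full: RegressionResult, refit: RegressionResult):
    f = full.exposure_terms().set_index(["category", "term"])
    r = refit.exposure_terms().set_index(["category", "term"])
    rows = []
    for key in f.index:
        or_full = f.loc[key, "or_"]
        or_refit = r.loc[key, "or_"]
        pct = 100.0 * (or_refit - or_full) / or_full
        rows.append(
            {
                "model": name,
                "method": method,
                "category": key[0],
                "term": key[1],
                "or_full": or_full,
                "or_refit": or_refit,
                "pct_change": pct,
                "meaningful": abs(pct) > 10.0,
            }
        )
    return rows


def refit_without_outliers(
    analytic: pd.DataFrame,
    outlier_tracts: dict[str, set] | set,
    full_results: dict[str, RegressionResult] | None = None,
) -> pd.DataFrame:
    """Refit the six primary models without respondents in outlier tracts.

    ``outlier_tracts`` is either one tract set or a {method label: set}
    mapping. Returns per-term OR percentage changes versus the full-sample
    fits, flagging |change| > 10%. Models whose outcome collapses to a single
    category after removal are skipped with a ``failed`` row.
    """
    if not isinstance(outlier_tracts, dict):
        outlier_tracts = {"removed": set(outlier_tracts)}
    full_results = full_results or fit_primary_models(analytic)
    rows: list[dict] = []
    for method, tracts in outlier_tracts.items():
        sub = analytic[~analytic["tract_id"].isin(tracts)]
        for name, full_res in full_results.items():
            try:
                if full_res.outcome == "ff_intake":
                    refit = fit_multinomial(sub, full_res.exposure, adjusted=full_res.adjusted)
                else:
                    refit = fit_binary(sub, full_res.outcome, full_res.exposure, adjusted=full_res.adjusted)
            except ModelFitError as exc:
                rows.append(
                    {"model": name, "method": method, "category": "", "term": "", "or_full": np.nan,
                     "or_refit": np.nan, "pct_change": np.nan, "meaningful": False, "failed": str(exc)}
                )
                continue
            rows.extend(_or_change_rows(name, method, full_res, refit))
    out = pd.DataFrame(rows)
    if "failed" not in out.columns:
        out["failed"] = ""
    return out


def confounder_check(analytic: pd.DataFrame) -> pd.DataFrame:
    """Add trips/day to the obesity/diabetes models; report FF-exposure AOR
    percentage change, flagging |change| > 10% as meaningful confounding."""
    rows: list[dict] = []
    for exposure in PRIMARY_EXPOSURES:
        for outcome in ("obesity", "diabetes"):
            base = fit_binary(analytic, outcome, exposure, adjusted=True)
            ctrl = fit_binary(analytic, outcome, exposure, adjusted=True, extra_covariates=("scaled_trips_day",))
            rows.extend(_or_change_rows(f"{outcome}~{exposure}", "plus_trips_day", base, ctrl))
    return pd.DataFrame(rows)
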