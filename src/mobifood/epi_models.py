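"""Survey exclusions, descriptive comparison, logistic models, Akaike weights.

The analytic sample is built by sequential exclusion (missing residence, rural
residence, missing study variables). FF intake (never / infrequent / moderate
/ frequent) is modelled with multinomial logistic regression against a scaled
neighborhood exposure, reference category "never"; obesity and diabetes with
binary logistic regression. Adjusted models add age group, gender,
race/ethnicity, education and income as treatment-coded categorical
covariates. Non-nested candidate models are compared by Akaike weights
w_i = exp(-Delta_i / 2) / sum_k exp(-Delta_k / 2), Delta_i = AIC_i - min AIC.

Model fitting is maximum likelihood via statsmodels (MNLogit / Logit);
confidence intervals are Wald on the log-odds scale. AIC is computed here as
-2 loglik + 2k with k the number of estimated coefficients including
intercepts (for the multinomial, summed over outcome-category blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

INTAKE_LEVELS = ["never", "infrequent", "moderate", "frequent"]
ADJUSTMENT_COVARIATES = ["age_group", "gender", "race_ethnicity", "education", "income"]
STUDY_VARIABLES = ADJUSTMENT_COVARIATES + ["ff_intake", "obesity", "diabetes"]

Z95 = float(stats.norm.ppf(0.975))


class ModelFitError(RuntimeError):
    """Raised when a model cannot be estimated (non-convergence, separation,
    constant exposure, degenerate outcome), with diagnostics in the message."""


@dataclass
class RegressionResult:
    model_id: str
    outcome: str
    exposure: str
    adjusted: bool
    table: pd.DataFrame  # category, term, coef, se, or_, ci_low, ci_high, p
    aic: float
    loglik: float
    k: int
    n: int

    def exposure_terms(self) -> pd.DataFrame:
        return self.table[self.table["term"].str.startswith(self.exposure)]


@dataclass
class AkaikeComparison:
    aic: list[float]
    deltas: list[float] = field(init=False)
    weights: list[float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aic) == 0:
            raise ValueError("need at least one AIC value")
        a = np.asarray(self.aic, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("AIC values must be finite")
        d = a - a.min()  # min-subtraction keeps the exponentials in range
        w = np.exp(-d / 2.0)
        self.deltas = d.tolist()
        self.weights = (w / w.sum()).tolist()


def akaike_weights(aic_values) -> AkaikeComparison:
    """Akaike weights over a candidate model set; weights sum to 1."""
    return AkaikeComparison(list(aic_values))


def apply_exclusions(
    respondents: pd.DataFrame, study_variables: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sequential sample exclusions with per-rule counts.

    Order: (1) missing residential information (no neighborhood id),
    (2) residence in a rural area, (3) missing data on any study variable.
    A record removed by an earlier rule is not recounted by a later one.
    """
    study_variables = study_variables or [c for c in STUDY_VARIABLES if c in respondents.columns]
    counts: dict[str, int] = {}
    t = respondents
    m = t["neighborhood_id"].isna()
    counts["missing_residence"] = int(m.sum())
    t = t[~m]
    r = t["rural"].astype(bool) if "rural" in t.columns else pd.Series(False, index=t.index)
    counts["rural"] = int(r.sum())
    t = t[~r]
    mv = t[study_variables].isna().any(axis=1)
    counts["missing_study_variable"] = int(mv.sum())
    t = t[~mv]
    return t.reset_index(drop=True), counts


def compare_samples(
    full: pd.DataFrame, analytic: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Descriptive full-vs-analytic comparison with chi-square tests.

    One row per (variable, category): counts and column percentages over
    non-missing values, plus the Pearson chi-square p-value for the
    full-vs-analytic x category contingency table of that variable (repeated
    across the variable's rows). A variable with a single non-empty category
    gets a NaN p-value and is flagged.
    """
    variables = variables or [c for c in STUDY_VARIABLES if c in full.columns]
    rows = []
    for var in variables:
        f = full[var].dropna()
        a = analytic[var].dropna()
        cats = sorted(set(f.unique()) | set(a.unique()), key=str)
        if var == "ff_intake":
            cats = [c for c in INTAKE_LEVELS if c in cats]
        fc = f.value_counts()
        ac = a.value_counts()
        table = np.array([[fc.get(c, 0) for c in cats], [ac.get(c, 0) for c in cats]])
        nonempty = table.sum(axis=0) > 0
        if nonempty.sum() >= 2:
            _, p, _, _ = stats.chi2_contingency(table[:, nonempty])
        else:
            p = np.nan
        for c in cats:
            rows.append(
                {
                    "variable": var,
                    "category": c,
                    "full_n": int(fc.get(c, 0)),
                    "full_pct": 100.0 * fc.get(c, 0) / len(f) if len(f) else np.nan,
                    "analytic_n": int(ac.get(c, 0)),
                    "analytic_pct": 100.0 * ac.get(c, 0) / len(a) if len(a) else np.nan,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _design(
    df: pd.DataFrame, exposure: str, adjusted: bool, extra_covariates: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Intercept + exposure + treatment-coded covariate dummies.

    A categorical exposure (ff_intake) is expanded to dummies against the
    first listed level; a continuous exposure enters as one column.
    """
    parts = [pd.Series(1.0, index=df.index, name="const")]
    if exposure == "ff_intake":
        cat = pd.Categorical(df["ff_intake"], categories=INTAKE_LEVELS)
        dum = pd.get_dummies(cat, prefix="ff_intake", drop_first=True, dtype=float)
        dum.index = df.index
        parts.append(dum)
    else:
        x = pd.to_numeric(df[exposure])
        if np.nanstd(x.to_numpy(float)) == 0:
            raise ModelFitError(f"exposure {exposure!r} is constant: coefficient inestimable")
        parts.append(x.rename(exposure))
    cov = (list(ADJUSTMENT_COVARIATES) if adjusted else []) + list(extra_covariates)
    for c in cov:
        if df[c].dtype.kind in "OUSb" or isinstance(df[c].dtype, pd.CategoricalDtype):
            dum = pd.get_dummies(df[c].astype("category"), prefix=c, drop_first=True, dtype=float)
            dum.index = df.index
            parts.append(dum)
        else:
            parts.append(pd.to_numeric(df[c]).rename(c))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        raise ModelFitError("design matrix contains missing values; apply exclusions first")
    return X


def _check_fit(res, model_id: str) -> None:
    converged = res.mle_retvals.get("converged", True)
    bse = np.asarray(res.bse, dtype=float)
    if not converged or not np.all(np.isfinite(bse)):
        raise ModelFitError(f"{model_id}: optimizer failed to converge (possible separation)")
    if np.nanmax(bse) > 50:
        raise ModelFitError(f"{model_id}: implausible standard errors (max {np.nanmax(bse):.1f}); separation likely")


def fit_multinomial(
    analytic: pd.DataFrame, exposure: str, adjusted: bool = False
) -> RegressionResult:
    """Multinomial logit of FF intake (reference "never") on a scaled exposure.

    Returns per-category ORs with Wald 95% CIs for every non-reference
    outcome category. Adjusted fits add the five sociodemographic covariates.
    """
    y = pd.Categorical(analytic["ff_intake"], categories=INTAKE_LEVELS, ordered=True)
    if pd.isna(y.codes).any() or (y.codes < 0).any():
        raise ModelFitError("ff_intake contains values outside the code list")
    observed = [lvl for lvl in INTAKE_LEVELS if lvl in set(analytic["ff_intake"])]
    if not observed:
        raise ModelFitError("analytic sample is empty")
    if observed[0] != "never":
        raise ModelFitError('reference category "never" absent from the sample')
    if len(observed) < 2:
        raise ModelFitError("ff_intake has a single observed category")
    X = _design(analytic, exposure, adjusted)
    model_id = f"multinomial:ff_intake~{exposure}{'+adj' if adjusted else ''}"
    try:
        res = sm.MNLogit(y.codes, X.to_numpy(float)).fit(
            method="newton", maxiter=500, tol=1e-8, disp=0
        )
    except Exception as exc:  # singular Hessian, perfect separation, ...
        raise ModelFitError(f"{model_id}: {exc}") from exc
    _check_fit(res, model_id)
    params = np.asarray(res.params)  # (k_terms, J-1), columns follow observed order
    bse = np.asarray(res.bse)
    rows = []
    for j, cat in enumerate(observed[1:]):
        for t, term in enumerate(X.columns):
            b, s = params[t, j], bse[t, j]
            rows.append(_term_row(cat, term, b, s))
    table = pd.DataFrame(rows)
    k = params.size
    aic = -2.0 * res.llf + 2.0 * k
    return RegressionResult(model_id, "ff_intake", exposure, adjusted, table, aic, res.llf, k, len(analytic))


def fit_binary(
    analytic: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjusted: bool = True,
    extra_covariates: tuple[str, ...] = (),
) -> RegressionResult:
    """Binary logistic regression of obesity or diabetes on an exposure.

    ``exposure`` is a continuous contextual column or "ff_intake" (expanded
    to category dummies vs never). ``extra_covariates`` supports the
    general-mobility confounder check (trips/day).
    """
    y = pd.to_numeric(analytic[outcome]).to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelFitError(f"outcome {outcome!r} must be binary 0/1")
    if y.min() == y.max():
        raise ModelFitError(f"outcome {outcome!r} has no variation (all {y[0]:.0f})")
    X = _design(analytic, exposure, adjusted, extra_covariates)
    model_id = f"logit:{outcome}~{exposure}{'+adj' if adjusted else ''}" + (
        "+" + "+".join(extra_covariates) if extra_covariates else ""
    )
    try:
        res = sm.Logit(y, X.to_numpy(float)).fit(method="newton", maxiter=500, tol=1e-8, disp=0)
    except Exception as exc:
        raise ModelFitError(f"{model_id}: {exc}") from exc
    _check_fit(res, model_id)
    rows = [_term_row("", term, b, s) for term, b, s in zip(X.columns, res.params, res.bse)]
    table = pd.DataFrame(rows)
    k = len(res.params)
    aic = -2.0 * res.llf + 2.0 * k
    return RegressionResult(model_id, outcome, exposure, adjusted, table, aic, res.llf, k, len(analytic))


def _term_row(category: str, term: str, b: float, s: float) -> dict:
    z = b / s if s > 0 else np.nan
    return {
        "category": category,
        "term": term,
        "coef": b,
        "se": s,
        "or_": float(np.exp(b)),
        "ci_low": float(np.exp(b - Z95 * s)),
        "ci_high": float(np.exp(b + Z95 * s)),
        "p": float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
    }
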