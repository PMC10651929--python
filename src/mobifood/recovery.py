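"""Simulation studies of estimator quality: coverage, bias, null calibration.

Each replicate draws a fresh survey sample from the synthetic world with
planted exposure log-odds, refits the corresponding model on the true scaled
exposure, and records the estimate, its Wald CI, and whether the CI covers
the planted value. These studies quantify what a single pipeline run cannot:
the frequentist operating characteristics of the regression layer.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from mobifood.epi_models import fit_binary, fit_multinomial
from mobifood.synthetic_world import WorldConfig, make_world, simulate_survey

_MOD = 2**31 - 1


def _replicate_seed(seed: int, r: int) -> int:
    return (seed * 100_003 + 7 * r + 1) % _MOD


def _survey_with_true_exposure(cfg: WorldConfig) -> pd.DataFrame:
    world = make_world(cfg)
    df = simulate_survey(world)
    x = df["neighborhood_id"].map(
        {n: world.truth.scaled_exposure(n) for n in world.truth.neighborhood_ff_propensity}
    )
    return df.assign(true_exposure=x), world


def recovery_study(
    n_replicates: int = 200, n: int = 5000, seed: int = 0, base_config: WorldConfig | None = None
) -> pd.DataFrame:
    """Coverage and bias of the planted intake and obesity exposure effects.

    Per replicate: fit the unadjusted multinomial (frequent vs never) and the
    unadjusted obesity logit on the true scaled exposure at sample size ``n``.
    Returns one row per (replicate, parameter) with the estimate, CI and
    coverage flag against the planted log-OR.
    """
    base = base_config or WorldConfig()
    rows = []
    for r in range(n_replicates):
        cfg = replace(base, n_respondents=n, seed=_replicate_seed(seed, r))
        df, world = _survey_with_true_exposure(cfg)
        ic = world.truth.intake_coefficients
        b_freq = ic["log_or_per_scaled_unit"][ic["categories"].index("frequent")]
        res_mn = fit_multinomial(df, "true_exposure", adjusted=False)
        row = res_mn.table[
            (res_mn.table["category"] == "frequent") & (res_mn.table["term"] == "true_exposure")
        ].iloc[0]
        rows.append(_record(r, "frequent_intake", b_freq, row))
        b_ob = world.truth.disease_coefficients["obesity"]["log_or_per_scaled_unit"]
        res_bi = fit_binary(df, "obesity", "true_exposure", adjusted=False)
        row = res_bi.table[res_bi.table["term"] == "true_exposure"].iloc[0]
        rows.append(_record(r, "obesity", b_ob, row))
    return pd.DataFrame(rows)


def _record(r: int, parameter: str, planted_log_or: float, row) -> dict:
    return {
        "replicate": r,
        "parameter": parameter,
        "planted_log_or": planted_log_or,
        "coef": row["coef"],
        "se": row["se"],
        "or_": row["or_"],
        "ci_low": row["ci_low"],
        "ci_high": row["ci_high"],
        "covered": bool(row["ci_low"] <= np.exp(planted_log_or) <= row["ci_high"]),
        "p": row["p"],
    }


def summarize_recovery(study: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter coverage, mean log-OR bias, and mean estimated OR."""
    out = []
    for parameter, grp in study.groupby("parameter", sort=True):
        out.append(
            {
                "parameter": parameter,
                "n_replicates": len(grp),
                "coverage": float(grp["covered"].mean()),
                "bias_log_or": float((grp["coef"] - grp["planted_log_or"]).mean()),
                "mean_or": float(grp["or_"].mean()),
            }
        )
    return pd.DataFrame(out)


def null_calibration_study(
    n_replicates: int = 200, n: int = 2000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Type-I error rate of the obesity exposure test under planted null effects."""
    base = WorldConfig(
        intake_log_or=(0.0, 0.0, 0.0), obesity_log_or=0.0, diabetes_log_or=0.0
    )
    rejections = 0
    for r in range(n_replicates):
        cfg = replace(base, n_respondents=n, seed=_replicate_seed(seed + 17, r))
        df, _ = _survey_with_true_exposure(cfg)
        res = fit_binary(df, "obesity", "true_exposure", adjusted=False)
        p = res.table.set_index("term").loc["true_exposure", "p"]
        rejections += int(p < alpha)
    return rejections / n_replicates
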