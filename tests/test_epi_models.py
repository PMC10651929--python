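import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mobifood.epi_models import (
    ADJUSTMENT_COVARIATES,
    INTAKE_LEVELS,
    ModelFitError,
    akaike_weights,
    apply_exclusions,
    compare_samples,
    fit_binary,
    fit_multinomial,
)


def survey_frame(n, rng, beta_freq=0.0, beta_ob=0.0, exposure=None):
    """Minimal analytic table with a continuous exposure and planted effects."""
    x = exposure if exposure is not None else rng.uniform(0.5, 3.5, n)
    df = pd.DataFrame({"id": range(n), "neighborhood_id": "A", "tract_id": "A-T0", "x": x})
    for c, cats in {
        "age_group": ["18-24", "40-49", "65+"],
        "gender": ["female", "male"],
        "race_ethnicity": ["white", "hispanic_latino", "asian"],
        "education": ["high_school", "college_or_postgraduate"],
        "income": ["low", "high"],
    }.items():
        df[c] = rng.choice(cats, n)
    logits = np.zeros((n, 4))
    logits[:, 3] = beta_freq * x
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    draw = rng.random(n)
    codes = (draw[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    df["ff_intake"] = np.array(INTAKE_LEVELS, dtype=object)[codes]
    df["obesity"] = (rng.random(n) < expit(-1.1 + beta_ob * x)).astype(float)
    df["diabetes"] = (rng.random(n) < expit(-2.1)).astype(float)
    df["rural"] = False
    return df


class TestExclusions:
    def test_sequential_rules_do_not_double_count(self):
        rng = np.random.default_rng(0)
        df = survey_frame(100, rng)
        df.loc[:9, "neighborhood_id"] = pd.NA  # rule 1: 10
        df.loc[5:14, "rural"] = True  # overlaps rule 1 on 5 rows -> rule 2 counts 5
        df.loc[12:19, "ff_intake"] = pd.NA  # overlaps rule 2 -> rule 3 counts 5
        analytic, counts = apply_exclusions(df)
        assert counts == {"missing_residence": 10, "rural": 5, "missing_study_variable": 5}
        assert len(analytic) == 80

    def test_clean_table_passes_through(self):
        df = survey_frame(50, np.random.default_rng(1))
        analytic, counts = apply_exclusions(df)
        assert len(analytic) == 50 and sum(counts.values()) == 0

    def test_all_missing_residence_empties_sample(self):
        df = survey_frame(20, np.random.default_rng(2))
        df["neighborhood_id"] = pd.NA
        analytic, counts = apply_exclusions(df)
        assert len(analytic) == 0
        assert counts == {"missing_residence": 20, "rural": 0, "missing_study_variable": 0}


class TestCompareSamples:
    def test_identical_samples_have_p_one(self):
        df = survey_frame(200, np.random.default_rng(3))
        out = compare_samples(df, df.copy())
        assert np.allclose(out["p_value"].dropna(), 1.0)
        assert (out["full_pct"] == out["analytic_pct"]).all()

    def test_percentages_computed_over_nonmissing(self):
        df = survey_frame(100, np.random.default_rng(4))
        df.loc[:19, "ff_intake"] = pd.NA
        out = compare_samples(df, df)
        intake = out[out["variable"] == "ff_intake"]
        assert intake["full_n"].sum() == 80
        assert intake["full_pct"].sum() == pytest.approx(100.0)

    def test_single_category_variable_flagged_undefined(self):
        df = survey_frame(50, np.random.default_rng(5))
        df["gender"] = "female"
        out = compare_samples(df, df, variables=["gender"])
        assert out["p_value"].isna().all()


class TestAkaikeWeights:
    def test_diabetes_column_reproduces_printed_weights(self):
        comp = akaike_weights([3353.8, 3355.4, 3374.4])
        assert comp.weights[0] == pytest.approx(0.69, abs=0.005)
        assert comp.weights[1] == pytest.approx(0.31, abs=0.005)
        assert comp.weights[2] == pytest.approx(2.3e-5, rel=0.05)

    def test_obesity_middle_weight(self):
        comp = akaike_weights([5754.7, 5750.2, 5777.9])
        assert comp.weights[1] == pytest.approx(0.90, abs=0.005)

    def test_equal_aics_share_weight_equally(self):
        assert akaike_weights([10.0, 10.0, 10.0]).weights == pytest.approx([1 / 3] * 3)

    def test_shift_invariance(self):
        a = [3353.8, 3355.4, 3374.4]
        assert akaike_weights(a).weights == pytest.approx(akaike_weights([x + 1e4 for x in a]).weights)

    def test_weights_sum_to_one_and_min_aic_dominates(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = list(rng.uniform(1000, 1100, 5))
            comp = akaike_weights(a)
            assert sum(comp.weights) == pytest.approx(1.0)
            assert np.argmax(comp.weights) == np.argmin(a)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            akaike_weights([])


class TestFits:
    def test_two_category_multinomial_equals_binary_logit(self):
        rng = np.random.default_rng(7)
        df = survey_frame(2000, rng, beta_freq=0.3)
        # collapse intake to frequent vs not, fit both routes
        df2 = df.copy()
        df2["frequent"] = (df2["ff_intake"] == "frequent").astype(float)
        df2["ff_intake"] = np.where(df2["frequent"] == 1.0, "infrequent", "never")
        mn = fit_multinomial(df2, "x", adjusted=False)
        bi = fit_binary(df2, "frequent", "x", adjusted=False)
        mrow = mn.table[(mn.table["category"] == "infrequent") & (mn.table["term"] == "x")].iloc[0]
        brow = bi.table[bi.table["term"] == "x"].iloc[0]
        assert mrow["coef"] == pytest.approx(brow["coef"], abs=1e-6)
        assert mrow["se"] == pytest.approx(brow["se"], abs=1e-6)

    def test_unadjusted_2x2_or_equals_cross_product_ratio(self):
        # hand-built 2x2: exposure 0/1, outcome 0/1
        a, b, c, d = 30, 70, 10, 90  # exposed cases, exposed non, unexposed cases, unexposed non
        df = pd.DataFrame(
            {
                "z": [1.0] * (a + b) + [0.0] * (c + d),
                "obesity": [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d,
            }
        )
        res = fit_binary(df, "obesity", "z", adjusted=False)
        row = res.table[res.table["term"] == "z"].iloc[0]
        assert row["or_"] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_constant_exposure_is_inestimable(self):
        df = survey_frame(200, np.random.default_rng(8), exposure=np.full(200, 2.0))
        with pytest.raises(ModelFitError, match="constant"):
            fit_multinomial(df, "x", adjusted=False)

    def test_degenerate_outcome_fails_clearly(self):
        df = survey_frame(200, np.random.default_rng(9))
        df["obesity"] = 0.0
        with pytest.raises(ModelFitError, match="no variation"):
            fit_binary(df, "obesity", "x", adjusted=False)

    def test_aic_counts_all_coefficient_blocks(self):
        rng = np.random.default_rng(10)
        df = survey_frame(1000, rng, beta_freq=0.2)
        res = fit_multinomial(df, "x", adjusted=False)
        assert res.k == 2 * 3  # (const + exposure) x 3 non-reference categories
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.k)

    def test_adjusted_fit_reports_covariate_terms(self):
        rng = np.random.default_rng(11)
        df = survey_frame(1500, rng, beta_ob=0.2)
        res = fit_binary(df, "obesity", "x", adjusted=True)
        terms = set(res.table["term"])
        assert "x" in terms
        assert any(t.startswith("age_group_") for t in terms)
        # reference categories excluded
        assert "gender_female" not in terms and "gender_male" in terms

    def test_null_covariates_leave_exposure_estimate_stable(self):
        # covariates independent of exposure: adjusted vs unadjusted within 10%
        rng = np.random.default_rng(12)
        df = survey_frame(4000, rng, beta_ob=np.log(1.5))
        un = fit_binary(df, "obesity", "x", adjusted=False)
        ad = fit_binary(df, "obesity", "x", adjusted=True)
        or_un = un.table.set_index("term").loc["x", "or_"]
        or_ad = ad.table.set_index("term").loc["x", "or_"]
        assert abs(or_ad - or_un) / or_un < 0.10
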