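"""Mixed-model residualization of abundances and coded genotypes."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from microscca import (
    FeatureTable,
    build_design,
    code_additive_dominance,
    gaussian_lmm_residuals,
    sample_tweedie,
    tweedie_glmm_residuals,
)
from microscca.lmm import FamilyBlocks, fit_lmm
from microscca.residualize import MixedModelResidualizer, validate_covariates

from conftest import make_genotypes


def _cov(n, rng, paired=True, n_ship=3):
    if paired:
        fams = np.repeat([f"F{i}" for i in range(n // 2)], 2)
    else:
        fams = [f"F{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "age": np.repeat(rng.uniform(40, 70, (n + 1) // 2), 2)[:n] if paired else rng.uniform(40, 70, n),
            "bmi": rng.normal(26, 4, n),
            "shipment": [f"s{rng.integers(n_ship)}" for _ in range(n)],
            "family_id": fams,
            "zygosity": "DZ",
        },
        index=[f"S{i:03d}" for i in range(n)],
    )


class TestDesign:
    def test_column_count(self, rng):
        cov = _cov(20, rng, n_ship=2)
        cov["PC1"] = rng.normal(size=20)
        cov["PC2"] = rng.normal(size=20)
        D = build_design(cov)
        # intercept + age + bmi + 1 shipment dummy + 2 PCs
        assert D.shape[1] == 6

    def test_full_rank_on_random_covariates(self, rng):
        cov = _cov(60, rng)
        D = build_design(cov)
        assert np.linalg.matrix_rank(D.to_numpy()) == D.shape[1]

    def test_single_shipment_level_omits_dummies(self, rng):
        cov = _cov(10, rng, n_ship=1)
        D = build_design(cov)
        assert not any(c.startswith("shipment") for c in D.columns)

    def test_constant_age_warns(self, rng):
        cov = _cov(10, rng)
        cov["age"] = 50.0
        with pytest.warns(UserWarning, match="constant"):
            D = build_design(cov)
        assert "age" in D.columns

    def test_family_size_cap_enforced(self, rng):
        cov = _cov(9, rng, paired=False)
        cov["family_id"] = "F0"
        with pytest.raises(ValueError, match="two members"):
            validate_covariates(cov)


class TestPairLmm:
    def test_fully_shared_column_absorbed_by_random_intercept(self, rng):
        """A column identical within every pair (and varying only between
        families) is explained by the family intercepts; conditional
        residuals shrink toward zero."""
        n = 100
        fams = np.repeat(np.arange(n // 2), 2)
        y = np.repeat(rng.normal(size=n // 2), 2)
        X = np.ones((n, 1))
        res = fit_lmm(y, X, FamilyBlocks(fams))
        assert np.abs(res["resid"]).max() < 0.05 * np.abs(y - y.mean()).max()

    def test_unrelated_cohort_reduces_to_ols(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(size=n)
        res = fit_lmm(y, X, FamilyBlocks(np.arange(n)))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res["beta"], beta_ols, atol=1e-10)
        assert res["theta"] == 0.0


class TestGaussianResiduals:
    def test_orthogonal_to_fixed_effect_design(self, rng, small_cohort):
        coded = code_additive_dominance(small_cohort.genotypes)
        resid = gaussian_lmm_residuals(coded, small_cohort.covariates)
        D = build_design(small_cohort.covariates).to_numpy()
        R = resid.values.to_numpy()
        corr = D[:, 1:].T @ R / len(R)  # skip intercept (columns centered)
        norm = np.outer(D[:, 1:].std(axis=0), R.std(axis=0)) + 1e-300
        assert np.abs(corr / norm).max() < 1e-6

    def test_pair_shared_column_shrinks_to_zero(self, rng):
        n = 120
        fams = np.repeat(np.arange(n // 2), 2)
        cov = _cov(n, rng)
        shared = np.repeat(rng.integers(0, 3, n // 2), 2).astype(float)
        calls = np.column_stack([shared, rng.integers(0, 3, n)]).astype(float)
        coded = code_additive_dominance(make_genotypes(calls))
        coded.columns.index = cov.index
        resid = gaussian_lmm_residuals(coded, cov)
        shared_resid = resid.values.iloc[:, 0].to_numpy()
        other_resid = resid.values.iloc[:, 2].to_numpy()
        assert np.abs(shared_resid).max() < 0.2 * np.abs(other_resid).max()

    def test_group_map_carried_through(self, small_cohort):
        coded = code_additive_dominance(small_cohort.genotypes)
        resid = gaussian_lmm_residuals(coded, small_cohort.covariates)
        pd.testing.assert_series_equal(resid.groups, coded.groups)


class TestTweedieResiduals:
    def test_planted_bmi_effect_removed(self, rng):
        n = 500
        cov = _cov(n, rng, paired=False)
        p, phi = 1.6, 0.5
        mu = np.exp(1.0 + 0.15 * (cov["bmi"] - cov["bmi"].mean()))
        y = sample_tweedie(mu.to_numpy(), phi, p, rng)
        table = FeatureTable(
            pd.DataFrame(y[None, :], index=["f0"], columns=cov.index)
        )
        resid = tweedie_glmm_residuals(table, cov, p)
        r = resid.values["f0"].to_numpy()
        raw_corr = np.corrcoef(y, cov["bmi"])[0, 1]
        assert abs(raw_corr) > 0.15  # effect planted
        assert abs(np.corrcoef(r, cov["bmi"])[0, 1]) < 0.05

    def test_intercept_only_model_preserves_ranks(self, rng):
        n = 60
        cov = _cov(n, rng, paired=False, n_ship=1)
        cov["age"] = 50.0
        cov["bmi"] = 25.0
        y = sample_tweedie(np.full(n, 3.0), 1.0, 1.5, rng)
        table = FeatureTable(pd.DataFrame(y[None, :], index=["f0"], columns=cov.index))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resid = tweedie_glmm_residuals(table, cov, 1.5)
        r = resid.values["f0"].to_numpy()
        order_y = np.argsort(y)
        assert (np.diff(r[order_y]) >= -1e-12).all()

    def test_twin_shared_intercepts_attenuated(self, rng):
        n = 300
        cov = _cov(n, rng, paired=True)
        fam_fx = np.repeat(rng.normal(0, 0.8, n // 2), 2)
        mu = np.exp(1.5 + fam_fx)
        y = sample_tweedie(mu, 2.0, 1.6, rng)
        table = FeatureTable(pd.DataFrame(y[None, :], index=["f0"], columns=cov.index))
        resid = tweedie_glmm_residuals(table, cov, 1.6)
        r = resid.values["f0"].to_numpy()

        def pair_corr(v):
            return np.corrcoef(v[0::2], v[1::2])[0, 1]

        assert pair_corr(y) > 0.3
        assert pair_corr(r) < 0.5 * pair_corr(y)

    def test_unrelated_matches_plain_glm_pearson_residuals(self, rng):
        n = 120
        cov = _cov(n, rng, paired=False)
        p = 1.5
        y = sample_tweedie(np.full(n, 4.0), 1.0, p, rng)
        table = FeatureTable(pd.DataFrame(y[None, :], index=["f0"], columns=cov.index))
        resid = tweedie_glmm_residuals(table, cov, p)
        D = build_design(cov)
        glm = sm.GLM(y, D.to_numpy(), family=sm.families.Tweedie(var_power=p)).fit()
        pearson = (y - glm.mu) / np.sqrt(glm.mu**p)
        pearson = pearson / np.sqrt((pearson**2).sum() / (n - D.shape[1]))
        pearson = pearson - pearson.mean()
        np.testing.assert_allclose(
            resid.values["f0"].to_numpy(), pearson, atol=1e-4
        )

    def test_all_zero_feature_rejected(self, rng):
        cov = _cov(20, rng)
        table = FeatureTable(
            pd.DataFrame(np.zeros((1, 20)), index=["f0"], columns=cov.index)
        )
        with pytest.raises(ValueError, match="zero"):
            tweedie_glmm_residuals(table, cov, 1.6)

    def test_power_outside_range_rejected(self, rng):
        cov = _cov(10, rng)
        table = FeatureTable(
            pd.DataFrame(np.ones((1, 10)), index=["f0"], columns=cov.index)
        )
        with pytest.raises(ValueError):
            tweedie_glmm_residuals(table, cov, 2.5)


def test_residualizer_estimator_matches_functions(rng, small_cohort):
    coded = code_additive_dominance(small_cohort.genotypes)
    ref = gaussian_lmm_residuals(coded, small_cohort.covariates)
    est = MixedModelResidualizer(kind="gaussian").fit(
        coded.columns, covariates=small_cohort.covariates
    )
    np.testing.assert_allclose(
        est.transform(coded.columns), ref.values.to_numpy(), atol=1e-10
    )
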