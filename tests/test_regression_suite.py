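"""Mixed and additive environmental-driver models: recovery and identities."""

import warnings

import numpy as np
import pandas as pd
import pytest

from leafquanta import regression_suite as rs
from leafquanta.synthetic_canopy import SyntheticConfig, simulate_campaign


@pytest.fixture(scope="module")
def covariates():
    """Microenvironment covariates from one dry-season campaign."""
    df = simulate_campaign(SyntheticConfig(seed=7, n_trees_per_stratum=15))
    return df[df["season"] == "dry"].reset_index(drop=True)


class TestFitLmm:
    def test_parameter_recovery_with_species_effects(self, covariates):
        rng = np.random.default_rng(0)
        z = (covariates["par"] - covariates["par"].mean()) / covariates["par"].std(ddof=1)
        codes = covariates["species"].astype("category").cat.codes.to_numpy()
        eff = rng.normal(0, 0.05, codes.max() + 1)
        y = 0.5 + 0.1 * z + eff[codes] + rng.normal(0, 0.01, len(covariates))
        fit = rs.fit_lmm(covariates.assign(resp=y), "resp")
        assert fit.coef["par"] == pytest.approx(0.1, abs=0.01)
        assert not fit.significant["vpd"] or abs(fit.coef["vpd"]) < 0.01
        assert fit.ci_low["height_m"] <= 0 <= fit.ci_high["height_m"]

    def test_deterministic_limit_exact(self, covariates):
        z = (covariates["vpd"] - covariates["vpd"].mean()) / covariates["vpd"].std(ddof=1)
        y = 0.3 + 0.2 * z
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_lmm(covariates.assign(resp=y), "resp")
        r2m, r2c = rs.r2_nakagawa(fit)
        assert fit.coef["vpd"] == pytest.approx(0.2, abs=1e-6)
        assert r2m == pytest.approx(1.0, abs=1e-6)
        assert r2c == pytest.approx(r2m, abs=1e-6)

    def test_independent_response_explains_nothing(self, covariates):
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 0.05, len(covariates))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_lmm(covariates.assign(resp=y), "resp")
        r2m, _ = rs.r2_nakagawa(fit)
        assert r2m < 0.02


class TestR2Nakagawa:
    def test_zero_random_variance_collapses(self):
        fit = rs.LmmFit("y", {}, {}, {}, {}, {}, var_fixed=2.0, var_random=0.0,
                        var_resid=1.0, n=10, n_groups=2, converged=True)
        r2m, r2c = rs.r2_nakagawa(fit)
        assert r2m == r2c

    def test_equal_components_forced_shares(self):
        fit = rs.LmmFit("y", {}, {}, {}, {}, {}, var_fixed=1.0, var_random=1.0,
                        var_resid=1.0, n=10, n_groups=2, converged=True)
        assert rs.r2_nakagawa(fit) == pytest.approx((1 / 3, 2 / 3))

    def test_configured_variance_components_recovered(self):
        rng = np.random.default_rng(5)
        n, n_sp = 5000, 40
        x = rng.normal(0, 1, n)
        sp = rng.integers(0, n_sp, n)
        eff = rng.normal(0, np.sqrt(0.5), n_sp)
        y = 1.0 * x + eff[sp] + rng.normal(0, np.sqrt(0.5), n)
        df = pd.DataFrame(dict(
            par=x, vpd=rng.normal(0, 1, n), height_m=rng.normal(0, 1, n),
            species=[f"s{i}" for i in sp], resp=y))
        r2m, r2c = rs.r2_nakagawa(rs.fit_lmm(df, "resp"))
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)


class TestVif:
    def test_independent_predictors_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (4000, 3)), columns=["a", "b", "c"])
        assert all(v == pytest.approx(1.0, abs=0.05)
                   for v in rs.vif(df, ("a", "b", "c")).values())

    def test_exact_collinearity_is_infinite(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(dict(a=rng.normal(0, 1, 100), b=rng.normal(0, 1, 100)))
        df["c"] = df["a"] + df["b"]
        with pytest.warns(UserWarning, match="collinear"):
            out = rs.vif(df, ("a", "b", "c"))
        assert np.isinf(out["c"])

    def test_partial_collinearity_closed_form(self):
        rng = np.random.default_rng(2)
        n = 200_00
        a = rng.normal(0, 1, n)
        b = np.sqrt(0.75) * a + np.sqrt(0.25) * rng.normal(0, 1, n)
        df = pd.DataFrame(dict(a=a, b=b, c=rng.normal(0, 1, n)))
        assert rs.vif(df, ("a", "b", "c"))["b"] == pytest.approx(4.0, rel=0.05)


class TestFitGamm:
    def test_constant_response_explains_nothing(self, covariates):
        df = covariates.assign(season="dry", resp=0.4)
        rng = np.random.default_rng(0)
        df["resp"] = np.clip(0.4 + rng.normal(0, 1e-3, len(df)), 0.01, 0.99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_gamm(df, "resp")
        assert fit.deviance_explained < 0.05
        for name, edf in fit.edf.items():
            if name.startswith("s("):
                assert edf < 1.6, name

    def test_linear_truth_shrinks_to_linear_smooth(self, covariates):
        rng = np.random.default_rng(3)
        z = (covariates["par"] - covariates["par"].mean()) / covariates["par"].std(ddof=1)
        mu = 1 / (1 + np.exp(-(0.2 + 0.5 * z)))
        y = np.clip(rng.beta(mu * 300, (1 - mu) * 300), 1e-6, 1 - 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_gamm(covariates.assign(resp=y), "resp")
        assert fit.edf["s(par):dry"] < 1.6

    def test_saturating_truth_recovered_within_band(self, covariates):
        rng = np.random.default_rng(4)
        par = covariates["par"].to_numpy()
        f = 1.2 * par / (par + 300.0)                  # saturating effect
        eta = -1.0 + f
        mu = 1 / (1 + np.exp(-eta))
        y = np.clip(rng.beta(mu * 200, (1 - mu) * 200), 1e-6, 1 - 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_gamm(covariates.assign(resp=y), "resp")
        lo, hi = np.percentile(par, [5, 95])
        grid = np.linspace(lo, hi, 40)
        est, se = fit.model.term_effect("s(par):dry", grid)
        truth = 1.2 * grid / (grid + 300.0)
        truth_c = truth - truth.mean()
        est_c = est - est.mean()
        assert np.all(np.abs(est_c - truth_c) < np.maximum(1.96 * se, 0.08) + 0.05)

    def test_boundary_values_squeezed_with_warning(self, covariates):
        y = np.full(len(covariates), 0.5)
        y[0], y[1] = 0.0, 1.0
        with pytest.warns(UserWarning, match="squeeze"):
            rs.fit_gamm(covariates.assign(resp=y), "resp")


class TestSmoothDifference:
    @pytest.fixture(scope="class")
    def two_season(self):
        df = simulate_campaign(SyntheticConfig(seed=9, n_trees_per_stratum=15))
        return df.reset_index(drop=True)

    def test_identical_seasonal_truths_rarely_significant(self, two_season):
        rng = np.random.default_rng(0)
        par = two_season["par"].to_numpy()
        mu = 1 / (1 + np.exp(-(-1.0 + par / 1500.0)))
        y = np.clip(rng.beta(mu * 150, (1 - mu) * 150), 1e-6, 1 - 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_gamm(two_season.assign(resp=y), "resp")
        d = rs.smooth_difference(fit, "par")
        assert d["significant"].mean() < 0.25

    def test_constructed_seasonal_shift_detected(self, two_season):
        rng = np.random.default_rng(1)
        par = two_season["par"].to_numpy()
        dry = (two_season["season"] == "dry").to_numpy()
        eta = -1.0 + par / 2000.0 + 0.4 * dry * (par < 900)
        mu = 1 / (1 + np.exp(-eta))
        y = np.clip(rng.beta(mu * 150, (1 - mu) * 150), 1e-6, 1 - 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_gamm(two_season.assign(resp=y), "resp")
        d = rs.smooth_difference(fit, "par")
        inside = d[d["x"] < 700]
        assert (inside["difference"] > 0).mean() > 0.9
        assert inside["significant"].mean() > 0.5

    def test_difference_against_self_is_zero(self, two_season):
        rng = np.random.default_rng(2)
        y = np.clip(rng.beta(40, 60, len(two_season)), 1e-6, 1 - 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_gamm(two_season.assign(resp=y), "resp")
        d = rs.smooth_difference(fit, "vpd", seasons=("dry", "dry"))
        np.testing.assert_allclose(d["difference"], 0.0, atol=1e-12)


class TestHierarchicalPartition:
    def test_single_predictor_share_equals_full_model(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = x + rng.normal(0, 1, 2000)
        df = pd.DataFrame(dict(a=x, y=y))
        shares = rs.hierarchical_partition(df, "y", predictors=("a",))
        m = rs.AdditiveModel("gaussian")
        m.add_smooth(x, k=5, name="a")
        m.fit(y)
        assert shares["a"] == pytest.approx(m.deviance_explained_, abs=1e-8)

    def test_orthogonal_predictors_recover_individual_shares(self):
        rng = np.random.default_rng(1)
        n = 3000
        a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = np.sqrt(0.3) * a + np.sqrt(0.2) * b + rng.normal(0, np.sqrt(0.5), n)
        df = pd.DataFrame(dict(a=a, b=b, y=y))
        shares = rs.hierarchical_partition(df, "y", predictors=("a", "b"))
        assert shares["a"] == pytest.approx(0.3, abs=0.04)
        assert shares["b"] == pytest.approx(0.2, abs=0.04)

    def test_irrelevant_predictor_share_near_zero(self):
        rng = np.random.default_rng(2)
        n = 2000
        a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = a + rng.normal(0, 0.5, n)
        shares = rs.hierarchical_partition(
            pd.DataFrame(dict(a=a, b=b, y=y)), "y", predictors=("a", "b"))
        assert shares["b"] < 0.02

    def test_shares_sum_to_full_model_deviance(self):
        rng = np.random.default_rng(3)
        n = 1500
        a = rng.normal(0, 1, n)
        b = 0.5 * a + rng.normal(0, 1, n)      # correlated predictors
        y = a + b + rng.normal(0, 1, n)
        df = pd.DataFrame(dict(a=a, b=b, y=y))
        shares = rs.hierarchical_partition(df, "y", predictors=("a", "b"))
        m = rs.AdditiveModel("gaussian")
        m.add_smooth(a, k=5, name="a")
        m.add_smooth(b, k=5, name="b")
        m.fit(y)
        assert sum(shares.values()) == pytest.approx(m.deviance_explained_,
                                                     abs=0.02)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 1000
        a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = a - 0.5 * b + rng.normal(0, 1, n)
        df = pd.DataFrame(dict(a=a, b=b, y=y))
        s1 = rs.hierarchical_partition(df, "y", predictors=("a", "b"))
        s2 = rs.hierarchical_partition(df, "y", predictors=("b", "a"))
        assert s1["a"] == pytest.approx(s2["a"], abs=1e-10)
        assert s1["b"] == pytest.approx(s2["b"], abs=1e-10)
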