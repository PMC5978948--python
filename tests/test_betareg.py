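"""Beta-regression engine against duplicate-formula and optimizer oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit, logit

from stockadmix.betareg import (
    aicc,
    apply_scaler,
    fit_betareg,
    fit_from_dict,
    fit_to_dict,
    loglik_beta,
    squeeze_unit_interval,
    standardize,
    vif,
)
from stockadmix.synthdata import LakeScenario, generate_lake_table


class TestStandardize:
    def test_three_point_column(self):
        design = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), ["x"])
        np.testing.assert_allclose(design.X[:, 1], [-1.0, 0.0, 1.0])
        assert design.term_names == ["(Intercept)", "x"]

    def test_idempotent_on_z_scores(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=50)
        z = (z - z.mean()) / z.std(ddof=1)
        design = standardize(pd.DataFrame({"x": z}), ["x"])
        np.testing.assert_allclose(design.X[:, 1], z, atol=1e-12)

    def test_scaler_round_trip(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame({"x": rng.uniform(5, 50, 30)})
        design = standardize(raw, ["x"])
        mean, sd = design.scaler["x"]
        np.testing.assert_allclose(design.X[:, 1] * sd + mean, raw["x"], atol=1e-10)

    def test_interaction_is_product_of_z_scores(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame({"a": rng.normal(10, 2, 40), "b": rng.normal(-3, 5, 40)})
        design = standardize(raw, ["a", "b", "a:b"])
        np.testing.assert_allclose(design.X[:, 3], design.X[:, 1] * design.X[:, 2], atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="'x'"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])

    def test_frozen_scaler_projection(self):
        raw = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        design = standardize(raw, ["x"])
        new = apply_scaler(pd.DataFrame({"x": [4.0]}), ["x"], design.scaler)
        assert new.X[0, 1] == pytest.approx(2.0)  # (4-2)/1


class TestLoglik:
    def test_uniform_density_is_zero(self):
        assert loglik_beta(np.array([0.5]), np.array([0.5]), 2.0) == pytest.approx(0.0)

    def test_mu_profile_maximum_solves_score_equation(self):
        """The mu-profile peaks where psi(mu phi) - psi((1-mu) phi) = logit(y)
        (an independent root-finding oracle), which tends to y as phi grows."""
        from scipy.optimize import brentq
        from scipy.special import digamma

        y = np.array([0.3])
        for phi in (7.0, 1e4):
            grid = np.linspace(0.02, 0.98, 1921)
            values = [loglik_beta(y, np.array([m]), phi) for m in grid]
            mu_grid = grid[int(np.argmax(values))]
            mu_oracle = brentq(
                lambda m: digamma(m * phi) - digamma((1 - m) * phi) - logit(y[0]),
                0.01, 0.99,
            )
            assert mu_grid == pytest.approx(mu_oracle, abs=1e-3)
        assert mu_oracle == pytest.approx(0.3, abs=1e-3)  # large-phi limit

    def test_matches_scipy_beta_logpdf(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            y = rng.uniform(0.01, 0.99, 5)
            mu = rng.uniform(0.05, 0.95, 5)
            phi = rng.uniform(0.2, 80)
            oracle = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()
            assert loglik_beta(y, mu, phi) == pytest.approx(oracle, rel=1e-10, abs=1e-10)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="squeeze"):
            loglik_beta(np.array([0.0, 0.5]), np.array([0.5, 0.5]), 2.0)

    def test_squeeze_only_touches_boundary_data(self):
        y = np.array([0.2, 0.8])
        np.testing.assert_array_equal(squeeze_unit_interval(y), y)
        squeezed = squeeze_unit_interval(np.array([0.0, 0.5, 1.0]))
        assert (squeezed > 0).all() and (squeezed < 1).all()


def _nelder_mead_oracle(X, y, k):
    """Independent derivative-free ML maximization over (beta, log phi)."""
    def nll(theta):
        mu = expit(X @ theta[:-1])
        return -loglik_beta(y, np.clip(mu, 1e-10, 1 - 1e-10), np.exp(theta[-1]))

    best = None
    for start_phi in (1.0, 2.5):
        theta0 = np.concatenate([np.zeros(k + 1), [start_phi]])
        theta0[0] = logit(np.mean(y))
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 50000, "maxfev": 50000})
        if best is None or res.fun < best.fun:
            best = res
    return best


class TestFit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_derivative_free_oracle(self, seed):
        scenario = LakeScenario(
            n_lakes=29, coefficients={"SinceMeanYear": -0.44, "MeanFishStock": 0.30},
            precision=20.0, seed=seed,
        )
        table = generate_lake_table(scenario)
        design = standardize(table, ["SinceMeanYear", "MeanFishStock"])
        y = table["qDomestic"].to_numpy()
        fit = fit_betareg(design, y)
        oracle = _nelder_mead_oracle(design.X, y, k=2)
        np.testing.assert_allclose(fit.beta, oracle.x[:-1], atol=1e-5)
        assert np.log(fit.phi) == pytest.approx(oracle.x[-1], abs=1e-4)
        assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-7)

    def test_matches_statsmodels_cross_check(self):
        from statsmodels.othermod.betareg import BetaModel

        table = generate_lake_table(LakeScenario(seed=5))
        design = standardize(table, ["SinceMeanYear", "MeanFishStock"])
        y = table["qDomestic"].to_numpy()
        fit = fit_betareg(design, y)
        sm = BetaModel(y, design.X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, sm.params[:-1], atol=1e-5)
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-6)
        np.testing.assert_allclose(fit.se, sm.bse[:-1], rtol=0.02)

    def test_loglik_not_below_start(self):
        table = generate_lake_table(LakeScenario(seed=6, precision=5.0))
        design = standardize(table, ["SinceMeanYear"])
        y = table["qDomestic"].to_numpy()
        fit = fit_betareg(design, y)
        # OLS-on-logit start
        z = np.log(y / (1 - y))
        beta0, *_ = np.linalg.lstsq(design.X, z, rcond=None)
        mu0 = expit(design.X @ beta0)
        assert fit.loglik >= loglik_beta(y, np.clip(mu0, 1e-9, 1 - 1e-9), fit.phi) - 1e-8

    def test_coefficient_recovery_single_replicate(self):
        scenario = LakeScenario(
            n_lakes=500, coefficients={"SinceMeanYear": -0.44}, precision=20.0, seed=7
        )
        table = generate_lake_table(scenario)
        fit = fit_betareg(standardize(table, ["SinceMeanYear"]), table["qDomestic"].to_numpy())
        j = fit.term_names.index("SinceMeanYear")
        assert abs(fit.beta[j] - (-0.44)) < 1.96 * fit.se[j]

    def test_equivariant_to_prescaling(self):
        table = generate_lake_table(LakeScenario(seed=8))
        y = table["qDomestic"].to_numpy()
        fit_raw = fit_betareg(standardize(table, ["SinceMeanYear"]), y)
        rescaled = table.copy()
        rescaled["SinceMeanYear"] = rescaled["SinceMeanYear"] * 37.0 + 4.0
        fit_scaled = fit_betareg(standardize(rescaled, ["SinceMeanYear"]), y)
        mu_a = expit(standardize(table, ["SinceMeanYear"]).X @ fit_raw.beta)
        mu_b = expit(standardize(rescaled, ["SinceMeanYear"]).X @ fit_scaled.beta)
        np.testing.assert_allclose(mu_a, mu_b, atol=1e-7)

    def test_adjusted_pseudo_r2_bounds_and_negativity(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame({"Depth": rng.uniform(2, 30, 25), "LakeSize": rng.uniform(5, 270, 25)})
        table["qDomestic"] = rng.beta(2, 20, 25)  # independent of predictors
        fit = fit_betareg(standardize(table, ["Depth", "LakeSize"]), table["qDomestic"].to_numpy())
        assert 0.0 <= fit.pseudo_r2 <= 1.0
        assert fit.adj_pseudo_r2 <= fit.pseudo_r2
        assert fit.adj_pseudo_r2 < 0.0  # uninformative predictors
        # Wherry correction holds exactly
        n, k = 25, 2
        assert fit.adj_pseudo_r2 == pytest.approx(
            1 - (1 - fit.pseudo_r2) * (n - 1) / (n - k - 1)
        )

    def test_too_few_observations_rejected(self):
        table = generate_lake_table(LakeScenario(seed=10)).head(3)
        with pytest.raises(ValueError, match="too small"):
            fit_betareg(standardize(table, ["SinceMeanYear", "TotalHa"]),
                        table["qDomestic"].to_numpy())

    def test_wald_p_uniform_under_null(self):
        """Two-sided normal p-values of a null slope are ~U(0,1) at n = 200."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            x = rng.normal(size=200)
            y = rng.beta(2.0, 8.0, size=200)
            table = pd.DataFrame({"Depth": x, "qDomestic": y})
            fit = fit_betareg(standardize(table, ["Depth"]), y)
            pvals.append(fit.p_values[fit.term_names.index("Depth")])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_serialization_round_trip(self):
        table = generate_lake_table(LakeScenario(seed=12))
        fit = fit_betareg(standardize(table, ["SinceMeanYear"]), table["qDomestic"].to_numpy())
        back = fit_from_dict(fit_to_dict(fit))
        np.testing.assert_allclose(back.beta, fit.beta)
        assert back.scaler == fit.scaler
        assert back.aicc == fit.aicc


class TestAicc:
    def test_worked_example(self):
        assert aicc(10.0, 3, 29) == pytest.approx(-14 + 24 / 25)

    def test_correction_vanishes_for_large_n(self):
        assert aicc(10.0, 3, 10**7) == pytest.approx(-14.0, abs=1e-4)

    def test_matches_textbook_formula_on_random_triples(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            ll = rng.normal(scale=50)
            df = int(rng.integers(1, 10))
            n = int(rng.integers(df + 2, 200))
            oracle = -2 * ll + 2 * df + (2 * df * (df + 1)) / (n - df - 1)
            assert aicc(ll, df, n) == pytest.approx(oracle, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestVif:
    def test_orthogonal_columns(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        diag = vif(pd.DataFrame({"a": a, "b": b}))
        assert diag.vif["a"] == pytest.approx(1.0)
        assert diag.vif["b"] == pytest.approx(1.0)

    def test_duplicate_column_infinite(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        with pytest.warns(UserWarning, match="collinearity"):
            diag = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(diag.vif["a"])

    def test_brute_force_auxiliary_regressions(self):
        rng = np.random.default_rng(15)
        base = rng.normal(size=(60, 5))
        base[:, 3] = 0.7 * base[:, 0] + 0.3 * rng.normal(size=60)
        cols = pd.DataFrame(base, columns=list("abcde"))
        diag = vif(cols)
        for j, name in enumerate(cols.columns):
            others = np.column_stack([np.ones(60), np.delete(base, j, axis=1)])
            yj = base[:, j]
            bhat = np.linalg.solve(others.T @ others, others.T @ yj)
            resid = yj - others @ bhat
            r2 = 1 - resid @ resid / np.sum((yj - yj.mean()) ** 2)
            assert diag.vif[name] == pytest.approx(1 / (1 - r2), rel=1e-8)
            assert diag.vif[name] >= 1.0

    def test_correlation_matrix_matches_pearsonr(self):
        rng = np.random.default_rng(16)
        cols = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("xyz"))
        diag = vif(cols)
        r, p = stats.pearsonr(cols["x"], cols["y"])
        assert diag.correlations.loc["x", "y"] == pytest.approx(r)
        assert diag.correlation_p.loc["x", "y"] == pytest.approx(p)
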