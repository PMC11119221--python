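"""Likelihood correctness: closed forms, independent oracles, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import mixedexplore as mx
from mixedexplore.fit import FitError


def dense_profiled_loglik(y, X, Z, groups, lam):
    """Independent oracle: profiled marginal log-likelihood at relative SD
    ``lam`` for a random-intercept model, via dense N x N linear algebra
    (no Woodbury, no per-group factorization)."""
    n = len(y)
    codes = pd.factorize(groups)[0]
    Zmat = np.zeros((n, codes.max() + 1))
    Zmat[np.arange(n), codes] = 1.0
    W = np.eye(n) + lam**2 * Zmat @ Zmat.T
    Wi = np.linalg.inv(W)
    beta = np.linalg.solve(X.T @ Wi @ X, X.T @ Wi @ y)
    r = y - X @ beta
    sigma2 = float(r @ Wi @ r) / n
    sign, logdet = np.linalg.slogdet(W)
    assert sign > 0
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


class TestFixedOnly:
    def test_intercept_only_two_points(self):
        df = pd.DataFrame({"y": [-1.0, 1.0]})
        m = mx.ModelFormula("y")
        r = mx.fit_fixed_only(m, df)
        assert r.beta == pytest.approx([0.0])
        assert r.sigma2 == pytest.approx(1.0)
        assert r.loglik == pytest.approx(-(math.log(2 * math.pi) + 1), abs=1e-12)

    def test_loglik_matches_ols_closed_form(self, sim_small):
        _, df = sim_small
        m = mx.parse_formula("y ~ x1 + x2")
        r = mx.fit_fixed_only(m, df)
        n = len(df)
        X = np.column_stack([np.ones(n), df["x1"], df["x2"]])
        beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        rss = float(((df["y"].to_numpy() - X @ beta) ** 2).sum())
        expected = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1)
        assert r.loglik == pytest.approx(expected, abs=1e-10)
        assert r.n_params == 4  # 3 coefficients + residual variance

    def test_coefficients_near_truth(self, sim_small):
        spec, df = sim_small
        r = mx.fit_fixed_only(mx.parse_formula("y ~ x1 + x2"), df)
        # OLS on mixed data is consistent for beta; loose 3-sigma-ish check
        assert r.beta[1] == pytest.approx(spec.beta["x1"], abs=0.3)
        assert r.beta[2] == pytest.approx(spec.beta["x2"], abs=0.3)

    def test_degenerate_designs_raise(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(FitError, match="rank deficient"):
            mx.fit_fixed_only(mx.parse_formula("y ~ x"), df)
        exact = pd.DataFrame({"y": [1.0, 2.0, 4.0], "x": [1.0, 2.0, 4.0]})
        with pytest.raises(FitError, match="perfect fit"):
            mx.fit_fixed_only(mx.parse_formula("y ~ x"), exact)
        tiny = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        with pytest.raises(FitError, match="observations"):
            mx.fit_fixed_only(mx.parse_formula("y ~ x"), tiny)

    def test_categorical_treatment_coding(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "y": rng.standard_normal(30),
            "c": np.tile(["a", "b", "z"], 10),
        })
        r = mx.fit_fixed_only(mx.parse_formula("y ~ c"), df)
        assert r.fixed_names == ("(Intercept)", "c[b]", "c[z]")
        assert r.n_params == 4  # intercept + 2 levels + residual variance


class TestInformationCriteria:
    def test_direct_arithmetic(self):
        aic, bic = mx.information_criteria(-100.0, 3, 100)
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200 + 3 * math.log(100), abs=1e-10)

    def test_log_one_edge(self):
        aic, bic = mx.information_criteria(0.0, 1, 1)
        assert (aic, bic) == (2.0, 0.0)
        with pytest.raises(ValueError):
            mx.information_criteria(0.0, 0, 1)

    def test_nonfinite_loglik_gives_missing(self):
        aic, bic = mx.information_criteria(float("nan"), 2, 10)
        assert math.isnan(aic) and math.isnan(bic)

    def test_bic_at_least_aic_beyond_e_squared(self, sim_small):
        _, df = sim_small
        r = mx.fit_fixed_only(mx.parse_formula("y ~ x1"), df)
        assert r.n_obs > math.e**2
        assert r.bic >= r.aic


class TestLmm:
    def test_boundary_equivalence_with_ols(self):
        """With zero true random-intercept variance the mixed fit collapses
        to the OLS likelihood and is flagged singular."""
        spec = mx.SimSpec(
            n_groups=12, group_sizes=25,
            beta={"(Intercept)": 0.5, "x1": 1.0},
            psi=((0.0,),), sigma=1.0, seed=11,
        )
        df = mx.simulate_dataset(spec)
        m_mixed = mx.parse_formula("y ~ x1", group="group")
        m_fixed = mx.parse_formula("y ~ x1")
        r_mixed = mx.fit_lmm(m_mixed, df)
        r_fixed = mx.fit_fixed_only(m_fixed, df)
        assert r_mixed.singular
        assert r_mixed.loglik == pytest.approx(r_fixed.loglik, abs=1e-6)

    def test_toy_fixture_matches_dense_grid_oracle(self, toy_lmm_data):
        """Profiled-ML fit on the 30-row, 3-group fixture agrees with an
        independent dense-matrix grid+polish maximization to 1e-4."""
        m = mx.parse_formula("y ~ x", group="g")
        r = mx.fit_lmm(m, toy_lmm_data)
        y = toy_lmm_data["y"].to_numpy()
        X = np.column_stack([np.ones(30), toy_lmm_data["x"].to_numpy()])
        g = toy_lmm_data["g"].to_numpy()
        grid = np.arange(0.0, 6.0, 0.01)
        lls = [dense_profiled_loglik(y, X, None, g, lam) for lam in grid]
        best = grid[int(np.argmax(lls))]
        res = minimize_scalar(
            lambda lam: -dense_profiled_loglik(y, X, None, g, lam),
            bracket=(max(best - 0.01, 0.0), best, best + 0.01),
        )
        assert r.loglik == pytest.approx(-res.fun, abs=1e-4)
        assert r.converged and not r.singular

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_statsmodels_on_random_toys(self, seed):
        """Marginal ML log-likelihood agrees with statsmodels MixedLM
        (an independent fitter) on small random slope-model datasets."""
        sm_mlm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        spec = mx.SimSpec(
            n_groups=10, group_sizes=20,
            beta={"(Intercept)": 1.0, "x1": 0.6, "x2": -0.4},
            psi=((0.8, 0.1), (0.1, 0.3)), sigma=0.9,
            slope_terms=("x1",), seed=seed,
        )
        df = mx.simulate_dataset(spec)
        r = mx.fit_lmm(
            mx.parse_formula("y ~ x1 + x2", group="group", slopes=["x1"]), df
        )
        fit = sm_mlm.MixedLM.from_formula(
            "y ~ x1 + x2", df, groups=df["group"], re_formula="~x1"
        ).fit(reml=False)
        # our profiled optimum should be at least as good, within tolerance
        assert r.loglik >= fit.llf - 1e-4
        assert r.loglik == pytest.approx(fit.llf, abs=1e-3)

    def test_variance_component_recovery(self):
        """Averaged over replicates (the estimator's sampling SD for a
        variance of 1 with 40 groups is ~0.25), recovered components land
        within 25% of the generating values."""
        psis, sigmas = [], []
        for seed in range(5):
            spec = mx.SimSpec(
                n_groups=40, group_sizes=50,
                beta={"(Intercept)": 1.0, "x1": 0.8},
                psi=((1.0, 0.0), (0.0, 0.25)), sigma=1.0,
                slope_terms=("x1",), seed=seed,
            )
            df = mx.simulate_dataset(spec)
            r = mx.fit_lmm(
                mx.parse_formula("y ~ x1", group="group", slopes=["x1"]), df
            )
            assert r.n_params == 2 + 3 + 1  # beta, tril(psi), residual
            psis.append(r.psi)
            sigmas.append(r.sigma2)
        mean_psi = np.mean(psis, axis=0)
        assert mean_psi[0, 0] == pytest.approx(1.0, rel=0.25)
        assert mean_psi[1, 1] == pytest.approx(0.25, rel=0.25)
        assert np.mean(sigmas) == pytest.approx(1.0, rel=0.1)

    def test_loglik_invariant_to_relabeling_and_row_order(self, sim_small):
        _, df = sim_small
        m = mx.parse_formula("y ~ x1 + x2", group="group", slopes=["x1"])
        base = mx.fit_lmm(m, df)
        relabeled = df.assign(group="zz_" + df["group"].astype(str))
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert mx.fit_lmm(m, relabeled).loglik == pytest.approx(base.loglik, abs=1e-8)
        assert mx.fit_lmm(m, shuffled).loglik == pytest.approx(base.loglik, abs=1e-8)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"y": np.arange(10.0), "x": np.arange(10.0) % 3,
                           "g": ["only"] * 10})
        with pytest.raises(FitError, match="two groups"):
            mx.fit_lmm(mx.parse_formula("y ~ x", group="g"), df)

    def test_nesting_monotonicity_fixed_models(self, sim_small):
        """Adding a predictor never decreases the maximized log-likelihood
        for nested fixed-effects models on identical rows."""
        _, df = sim_small
        formulas = ["y ~ 1", "y ~ x1", "y ~ x1 + x2"]
        lls = [
            mx.fit_fixed_only(mx.parse_formula(f), df).loglik for f in formulas
        ]
        assert lls == sorted(lls)

    def test_criteria_identity_on_stored_fields(self, sim_small):
        _, df = sim_small
        r = mx.fit_lmm(mx.parse_formula("y ~ x1", group="group", slopes=["x1"]), df)
        assert r.aic == pytest.approx(-2 * r.loglik + 2 * r.n_params, abs=1e-10)
        assert r.bic == pytest.approx(
            -2 * r.loglik + r.n_params * math.log(r.n_obs), abs=1e-10
        )
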