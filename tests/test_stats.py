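"""Correlation, regression, collinearity and sensitivity machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emogo.stats import (bonferroni, bonferroni_reject, critical_r,
                         detectable_rho, hierarchical_regression,
                         partial_correlation, pearson, vif)


class TestPearson:
    def test_perfect_linear_relations(self, rng):
        x = rng.normal(size=50)
        assert pearson(x, 2 * x + 3).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_scipy_p_value(self, rng):
        x, y = rng.normal(size=(2, 40))
        res = pearson(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp)
        assert res.p == pytest.approx(p_sp, rel=1e-6)

    def test_large_sample_recovery_of_rho(self, rng):
        rho = 0.64
        cov = np.array([[1, rho], [rho, 1]])
        xy = rng.multivariate_normal([0, 0], cov, size=5000)
        assert pearson(xy[:, 0], xy[:, 1]).r == pytest.approx(rho, abs=0.03)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=(2, 60))
        base = pearson(x, y).r
        assert pearson(5 * x - 2, y).r == pytest.approx(base, abs=1e-12)
        assert pearson(x, 0.1 * y + 7).r == pytest.approx(base, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_significance_matches_critical_r_threshold(self, rng):
        n, alpha = 53, 0.05
        rc = critical_r(n, alpha)
        for target in (rc - 0.02, rc + 0.02):
            x = rng.normal(size=n)
            y = target * x + np.sqrt(1 - target**2) * rng.normal(size=n)
            # rescale to hit the sample r exactly
            res = pearson(x, y)
            # decision must agree with |r| vs critical r
            assert (res.p < alpha) == (abs(res.r) > rc - 1e-12)


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        a = partial_correlation(x, y, np.empty((40, 0)))
        b = pearson(x, y)
        assert a.r == pytest.approx(b.r) and a.df == b.df

    def test_binary_covariate_absorbs_group_difference(self, rng):
        n = 4000
        g = rng.integers(0, 2, size=n).astype(float)
        x = rng.normal(size=n)
        y = g * 2.0 + 0.01 * rng.normal(size=n)
        res = partial_correlation(x, y, g)
        assert abs(res.r) < 0.05
        assert res.df == n - 3

    def test_shared_covariate_explains_spurious_association(self, rng):
        n = 4000
        c = rng.normal(size=n)
        x = c + rng.normal(size=n)
        y = c + rng.normal(size=n)
        assert pearson(x, y).r > 0.3
        assert abs(partial_correlation(x, y, c).r) < 0.05

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 80
        df = pd.DataFrame(dict(x=rng.normal(size=n), y=rng.normal(size=n),
                               c1=rng.normal(size=n), c2=rng.normal(size=n)))
        df["y"] += 0.5 * df["c1"]
        df["x"] += 0.3 * df["c1"]
        res = partial_correlation(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.normal(size=(2, 30))
        c = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 1, 0.05), (0.05, 5, 0.01), (0.05, 3, 0.05 / 3),
    ])
    def test_corrected_alpha(self, alpha, m, expected):
        assert bonferroni(alpha, m) == pytest.approx(expected)

    def test_family_decisions(self):
        assert bonferroni_reject([0.001, 0.02, 0.04], alpha=0.05).tolist() == \
            [True, False, False]


class TestCriticalR:
    def test_study_sensitivity_threshold(self):
        assert critical_r(53, 0.05) == pytest.approx(0.271, abs=5e-4)

    def test_alpha_to_one_limit(self):
        assert critical_r(53, 0.999) < 0.001

    def test_tiny_sample_against_quantile_oracle(self):
        t = sps.t.ppf(0.975, 2)
        assert critical_r(4, 0.05) == pytest.approx(t / np.sqrt(t * t + 2), abs=1e-12)

    def test_detectable_rho_exceeds_significance_threshold(self):
        # the power-based detectable effect is necessarily larger
        assert detectable_rho(53, 0.05, 0.95) > critical_r(53, 0.05)


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        # Helmert contrasts: exactly orthogonal, zero-mean columns
        n = 60
        cols = {}
        for k, name in enumerate(("a", "b", "c"), start=1):
            v = np.zeros(n)
            v[:k] = 1.0
            v[k] = -k
            cols[name] = v
        out = vif(pd.DataFrame(cols))
        assert np.allclose(out, 1.0, atol=1e-8)

    def test_near_duplicate_predictor_explodes(self, rng):
        x = rng.normal(size=200)
        out = vif(pd.DataFrame(dict(a=x, b=x + 1e-4 * rng.normal(size=200))))
        assert (out > 10).all()

    def test_equicorrelated_design_matches_closed_form(self, rng):
        # three predictors with pairwise rho=0.5: R_j^2 = 2*rho^2/(1+rho) = 1/3
        n = 120_000
        c = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        x = rng.multivariate_normal(np.zeros(3), c, size=n)
        out = vif(pd.DataFrame(x, columns=list("abc")))
        assert np.allclose(out, 1.5, atol=0.05)


class TestHierarchicalRegression:
    def test_perfect_step1_leaves_nothing_to_add(self, rng):
        x1 = rng.normal(size=50)
        z = rng.normal(size=50)
        res = hierarchical_regression(x1, pd.DataFrame(dict(x1=x1)),
                                      pd.DataFrame(dict(z=z)))
        assert res.steps[0].r2 == pytest.approx(1.0)
        assert res.delta_r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_matrix_algebra_oracle(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(size=n)
        s1 = pd.DataFrame(X[:, :2], columns=["a", "b"])
        s2 = pd.DataFrame(X[:, 2:], columns=["c"])
        res = hierarchical_regression(y, s1, s2)

        def r2(Xsub):
            D = np.column_stack([np.ones(n), Xsub])
            beta = np.linalg.solve(D.T @ D, D.T @ y)
            resid = y - D @ beta
            return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        r2_1, r2_f = r2(X[:, :2]), r2(X)
        assert res.steps[0].r2 == pytest.approx(r2_1, abs=1e-10)
        assert res.steps[1].r2 == pytest.approx(r2_f, abs=1e-10)
        expect_df = ((r2_f - r2_1) / 1) / ((1 - r2_f) / (n - 3 - 1))
        assert res.delta_f == pytest.approx(expect_df, abs=1e-8)

    def test_delta_f_equals_t_squared_for_single_addition(self, rng):
        n = 80
        d = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = d["a"] + 0.5 * d["c"] + rng.normal(size=n)
        res = hierarchical_regression(y.to_numpy(), d[["a", "b"]], d[["c"]])
        t_c = res.steps[1].coef.loc["c", "t"]
        assert res.delta_f == pytest.approx(t_c ** 2, rel=1e-10)
        assert res.delta_f >= 0
        assert res.steps[1].r2 >= res.steps[0].r2

    def test_duplicated_predictor_is_an_error(self, rng):
        d = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            hierarchical_regression(y, d[["a"]], d[["a"]])
        dup = d.copy()
        dup["c"] = dup["a"]
        with pytest.raises(ValueError, match="collinear|Collinear"):
            hierarchical_regression(y, dup[["a", "b"]], dup[["c"]])

    def test_standardized_betas_are_scale_free(self, rng):
        n = 100
        d = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = (2 * d["a"] - d["b"] + rng.normal(size=n)).to_numpy()
        res1 = hierarchical_regression(y, d[["a"]], d[["b"]])
        scaled = d.copy()
        scaled["a"] = scaled["a"] * 100
        res2 = hierarchical_regression(y, scaled[["a"]], scaled[["b"]])
        assert res1.steps[1].coef.loc["a", "beta"] == pytest.approx(
            res2.steps[1].coef.loc["a", "beta"], abs=1e-10)
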