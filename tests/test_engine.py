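"""Estimation engine: discrepancy function, gradients, standard errors,
standardization — each checked against an independent route (closed forms,
textbook regression, finite differences, direct sandwich computation)."""

import numpy as np
import pandas as pd
import pytest

from realist_sem import (ClusteredDataset, ConceptBinding, FitOptions,
                         build_sem_from_cmos, fit_ml, fit_ml_cov,
                         model_implied_covariance, sample_covariance,
                         standardize)
from realist_sem.cfa import one_factor_model
from realist_sem.engine import (_f_and_grad, casewise_scores,
                                cluster_robust_vcov, default_start,
                                expected_information, naive_vcov)
from realist_sem.model_spec import SemModel
from realist_sem.synthetic import paper_model_cmos, paper_fixture, \
    generate_linked_dataset

from conftest import make_factor_data, observed


# ---------------------------------------------------------------------------
# sample covariance
# ---------------------------------------------------------------------------

class TestSampleCovariance:
    def _data(self, cols):
        frame = pd.DataFrame(cols)
        frame["cl"] = np.arange(len(frame))
        return ClusteredDataset(frame, "cl")

    def test_identical_columns_share_variance(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        s = sample_covariance(self._data({"a": x, "b": x.copy()}), ["a", "b"])
        assert s[0, 1] == pytest.approx(s[0, 0])

    def test_negated_column_flips_sign(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        s = sample_covariance(self._data({"a": x, "b": -x}), ["a", "b"])
        assert s[0, 1] == pytest.approx(-s[0, 0])

    def test_matches_hand_summation_divisor_n(self):
        cols = {"a": np.array([1.0, 2.0, 3.0]),
                "b": np.array([2.0, 1.0, 6.0]),
                "c": np.array([0.0, 4.0, 5.0])}
        s = sample_covariance(self._data(cols), ["a", "b", "c"])
        n = 3
        for i, u in enumerate("abc"):
            for j, v in enumerate("abc"):
                xu, xv = cols[u], cols[v]
                brute = np.sum((xu - xu.mean()) * (xv - xv.mean())) / n
                assert s[i, j] == pytest.approx(brute)

    def test_zero_variance_names_variable(self):
        with pytest.raises(ValueError, match="b"):
            sample_covariance(
                self._data({"a": np.array([1.0, 2.0, 3.0]),
                            "b": np.ones(3)}), ["a", "b"])


# ---------------------------------------------------------------------------
# model-implied covariance
# ---------------------------------------------------------------------------

class TestImpliedCovariance:
    def test_identity_reduction_gives_psi(self):
        psi = np.array([[1.0, 0.3], [0.3, 2.0]])
        m = SemModel(
            observed_vars=["a", "b"], latent_vars=["la", "lb"],
            lam_val=np.eye(2), lam_free=np.zeros((2, 2), bool),
            b_val=np.zeros((2, 2)), b_free=np.zeros((2, 2), bool),
            psi_val=psi, psi_free=np.zeros((2, 2), bool),
            theta_val=np.zeros((2, 2)), theta_free=np.zeros((2, 2), bool))
        np.testing.assert_allclose(
            model_implied_covariance(np.empty(0), m), psi)

    def test_single_path_hand_algebra(self, regression_model):
        # y = 0.5 x, var(x) = 1, disturbance 0.75 -> unit variances, cov 0.5
        theta = np.array([0.5, 1.0, 0.75])  # order: b, psi_x, psi_y
        sigma = model_implied_covariance(theta, regression_model)
        np.testing.assert_allclose(sigma, [[1.0, 0.5], [0.5, 1.0]])

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_for_random_admissible_theta(self, seed):
        model = build_sem_from_cmos(paper_model_cmos())
        rng = np.random.default_rng(seed)
        s = np.eye(model.p)
        theta = default_start(model, s) + 0.05 * rng.standard_normal(model.q)
        sigma = model_implied_covariance(theta, model)
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)

    def test_singular_structural_matrix_raises(self, regression_model):
        model = regression_model
        model.b_val[0, 1] = 1.0   # with b_free y~x = 1 -> (I-B) singular? no:
        # force a genuinely singular (I-B): set both cross paths to 1
        theta = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="not invertible"):
            model_implied_covariance(theta, model)


# ---------------------------------------------------------------------------
# maximum likelihood fitting
# ---------------------------------------------------------------------------

class TestFitML:
    def test_factor_triad_closed_form(self):
        """Just-identified one-factor model: loading_1 = sqrt(s12 s13 / s23)."""
        b = ConceptBinding("f", "reflective", ("x1", "x2", "x3"))
        model = one_factor_model(b, identification="variance")
        s = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.48], [0.5, 0.48, 1.0]])
        fit = fit_ml_cov(model, s, n=500)
        assert fit.converged
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)
        lam1 = fit.theta_hat[fit.param_names.index("f=~x1")]
        assert lam1 == pytest.approx(np.sqrt(0.6 * 0.5 / 0.48), abs=1e-6)

    def test_saturated_model_zero_discrepancy(self, regression_model,
                                              regression_data):
        # free the covariance between the two exogenous-block latents:
        # the 2-variable regression model is already saturated (q = 3 = p*)
        fit = fit_ml(regression_model, regression_data)
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)

    def test_ols_equivalence(self, regression_model, regression_data):
        """ML point estimate and naive SE equal textbook ML regression."""
        fit = fit_ml(regression_model, regression_data)
        k = fit.param_names.index("yl~xl")
        x = regression_data.frame["x"].to_numpy()
        y = regression_data.frame["y"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        beta = xc @ yc / (xc @ xc)
        resid = yc - beta * xc
        se_ml = np.sqrt((resid @ resid) / len(x) / (xc @ xc))
        assert fit.theta_hat[k] == pytest.approx(beta, abs=1e-6)
        assert fit.naive_se[k] == pytest.approx(se_ml, abs=1e-6)

    def test_ols_equivalence_statsmodels(self, regression_model,
                                         regression_data):
        import statsmodels.api as sm
        fit = fit_ml(regression_model, regression_data)
        k = fit.param_names.index("yl~xl")
        x = sm.add_constant(regression_data.frame["x"].to_numpy())
        ols = sm.OLS(regression_data.frame["y"].to_numpy(), x).fit()
        assert fit.theta_hat[k] == pytest.approx(ols.params[1], abs=1e-6)

    def test_parameter_recovery_large_n(self):
        data = make_factor_data((0.8, 0.7, 0.6, 0.65), n=5000, seed=3)
        b = ConceptBinding("f", "reflective", ("x1", "x2", "x3", "x4"))
        model = one_factor_model(b, identification="variance")
        fit = fit_ml(model, data)
        assert fit.converged
        for lam, name in zip((0.8, 0.7, 0.6, 0.65),
                             ("x1", "x2", "x3", "x4")):
            est = fit.theta_hat[fit.param_names.index(f"f=~{name}")]
            assert abs(abs(est) - lam) < 0.06

    def test_discrepancy_invariant_to_variable_order(self):
        data = make_factor_data((0.8, 0.7, 0.6, 0.65), n=800, seed=4)
        inds = ("x1", "x2", "x3", "x4")
        fits = []
        for order in (inds, inds[::-1]):
            b = ConceptBinding("f", "reflective", order, reference="x1")
            fits.append(fit_ml(one_factor_model(b), data))
        assert fits[0].f_min == pytest.approx(fits[1].f_min, abs=1e-9)

    def test_not_positive_definite_sample_cov_raises(self):
        b = ConceptBinding("f", "reflective", ("x1", "x2", "x3"))
        model = one_factor_model(b)
        s = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml_cov(model, s, n=100)

    def test_gradient_matches_finite_differences(self):
        model = build_sem_from_cmos(paper_model_cmos())
        data = generate_linked_dataset(paper_fixture(), seed=3)
        complete, _ = data.complete_cases(model.observed_vars)
        s = sample_covariance(complete, model.observed_vars)
        _, logdet_s = np.linalg.slogdet(s)
        rng = np.random.default_rng(0)
        theta = default_start(model, s) + 0.01 * rng.standard_normal(model.q)
        _, g = _f_and_grad(theta, model, s, logdet_s)
        for k in rng.choice(model.q, size=25, replace=False):
            e = np.zeros(model.q); e[k] = 1e-6
            fp, _ = _f_and_grad(theta + e, model, s, logdet_s)
            fm, _ = _f_and_grad(theta - e, model, s, logdet_s)
            assert g[k] == pytest.approx((fp - fm) / 2e-6,
                                         abs=1e-6 + 1e-4 * abs(g[k]))


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

class TestStandardErrors:
    def test_doubling_data_shrinks_se_sqrt2(self, regression_model,
                                            regression_data):
        fit1 = fit_ml(regression_model, regression_data)
        doubled = pd.concat([regression_data.frame, regression_data.frame],
                            ignore_index=True)
        doubled["cl"] = np.arange(len(doubled))
        fit2 = fit_ml(regression_model, ClusteredDataset(doubled, "cl"))
        ratio = fit1.naive_se / fit2.naive_se
        np.testing.assert_allclose(ratio, np.sqrt(2), rtol=1e-4)

    def test_vcov_dimension_excludes_fixed(self, regression_model,
                                           regression_data):
        fit = fit_ml(regression_model, regression_data)
        assert fit.vcov_naive.shape == (regression_model.q,) * 2

    def test_scores_sum_to_total_gradient(self, regression_model,
                                          regression_data):
        """Casewise scores sum to -(n/2) * grad F at any parameter value."""
        fit = fit_ml(regression_model, regression_data)
        theta = fit.theta_hat + np.array([0.05, -0.02, 0.04])
        fit.theta_hat = theta
        scores = casewise_scores(fit, regression_model, regression_data)
        s = fit.sample_cov
        _, logdet_s = np.linalg.slogdet(s)
        _, g = _f_and_grad(theta, regression_model, s, logdet_s)
        np.testing.assert_allclose(scores.sum(axis=0), -(fit.n / 2) * g,
                                   rtol=1e-8, atol=1e-8)

    def test_size_one_clusters_equal_hc0(self, regression_model,
                                         regression_data):
        """Cluster sandwich with singleton clusters == HC0 computed directly
        from numerically differentiated casewise log-likelihoods."""
        fit = fit_ml(regression_model, regression_data)
        vr = fit.vcov_robust

        # independent oracle: per-case scores by finite differences of l_i
        x = regression_data.matrix(regression_model.observed_vars)
        z = x - x.mean(axis=0)

        def loglik_rows(theta):
            sigma = model_implied_covariance(theta, regression_model)
            sinv = np.linalg.inv(sigma)
            _, ld = np.linalg.slogdet(sigma)
            quad = np.einsum("ij,jk,ik->i", z, sinv, z)
            return -0.5 * (ld + quad)

        q = regression_model.q
        sc = np.empty((len(z), q))
        for k in range(q):
            e = np.zeros(q); e[k] = 1e-6
            sc[:, k] = (loglik_rows(fit.theta_hat + e)
                        - loglik_rows(fit.theta_hat - e)) / 2e-6
        from realist_sem.engine import _hessian_at_fit
        h = _hessian_at_fit(fit, regression_model)
        bread = np.linalg.inv(h) * (2.0 / fit.n)
        hc0 = bread @ (sc.T @ sc) @ bread
        np.testing.assert_allclose(vr, hc0, rtol=1e-4, atol=1e-10)

    def test_single_cluster_rejected(self, regression_model):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"x": rng.standard_normal(50),
                              "y": rng.standard_normal(50), "cl": 0})
        data = ClusteredDataset(frame, "cl")
        fit = fit_ml(regression_model, data)
        with pytest.raises(ValueError, match="single cluster"):
            cluster_robust_vcov(fit, regression_model, data)

    def test_robust_close_to_naive_without_clustering(self):
        """Independent data, correct model: robust/naive in [0.9, 1.1]."""
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        frame = pd.DataFrame({"x": x, "y": y,
                              "cl": np.arange(n) // 5})  # arbitrary grouping
        data = ClusteredDataset(frame, "cl")
        model = SemModel(
            observed_vars=["x", "y"], latent_vars=["xl", "yl"],
            lam_val=np.eye(2), lam_free=np.zeros((2, 2), bool),
            b_val=np.zeros((2, 2)),
            b_free=np.array([[False, False], [True, False]]),
            psi_val=np.zeros((2, 2)), psi_free=np.diag([True, True]),
            theta_val=np.zeros((2, 2)), theta_free=np.zeros((2, 2), bool),
            degenerate={"xl", "yl"})
        fit = fit_ml(model, data)
        ratio = fit.robust_se / fit.naive_se
        assert np.all(ratio > 0.9) and np.all(ratio < 1.1)

    def test_cluster_effect_inflates_robust_se(self):
        """A cluster-constant predictor with clustered residuals: the robust
        SE of its path must exceed the naive one."""
        rng = np.random.default_rng(6)
        g, size = 120, 15
        n = g * size
        assign = np.repeat(np.arange(g), size)
        xg = rng.standard_normal(g)
        x = xg[assign]
        u = rng.standard_normal(g)[assign]
        y = 0.4 * x + np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal(n)
        frame = pd.DataFrame({"x": x, "y": y, "cl": assign})
        data = ClusteredDataset(frame, "cl")
        model = SemModel(
            observed_vars=["x", "y"], latent_vars=["xl", "yl"],
            lam_val=np.eye(2), lam_free=np.zeros((2, 2), bool),
            b_val=np.zeros((2, 2)),
            b_free=np.array([[False, False], [True, False]]),
            psi_val=np.zeros((2, 2)), psi_free=np.diag([True, True]),
            theta_val=np.zeros((2, 2)), theta_free=np.zeros((2, 2), bool),
            degenerate={"xl", "yl"})
        fit = fit_ml(model, data)
        k = fit.param_names.index("yl~xl")
        assert fit.robust_se[k] > 1.5 * fit.naive_se[k]

    def test_expected_information_matches_hessian_at_good_fit(self):
        """At the optimum of a well-fitting model the expected information
        approximates the observed Hessian of F."""
        data = make_factor_data((0.8, 0.7, 0.6), n=4000, seed=9)
        b = ConceptBinding("f", "reflective", ("x1", "x2", "x3"))
        model = one_factor_model(b)
        fit = fit_ml(model, data)
        from realist_sem.engine import _hessian_at_fit
        h = _hessian_at_fit(fit, model)
        e = expected_information(model, fit.theta_hat)
        np.testing.assert_allclose(e, h, rtol=0.05, atol=1e-4)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_sd_ratio_arithmetic(self):
        """Unstandardized path 0.5 with sd(x) = 2, sd(y) = 1 -> beta = 1."""
        model = SemModel(
            observed_vars=["x", "y"], latent_vars=["xl", "yl"],
            lam_val=np.eye(2), lam_free=np.zeros((2, 2), bool),
            b_val=np.array([[0.0, 0.0], [0.5, 0.0]]),
            b_free=np.zeros((2, 2), bool),
            psi_val=np.diag([4.0, 0.0]), psi_free=np.zeros((2, 2), bool),
            theta_val=np.zeros((2, 2)), theta_free=np.zeros((2, 2), bool),
            degenerate={"xl", "yl"})
        # var(y) = 0.5^2 * 4 + 0 = 1, so beta = 0.5 * 2 / 1 = 1
        from realist_sem.engine import _std_vector, _report_items
        items = _report_items(model)
        std, sd_lat, sd_obs = _std_vector(np.empty(0), model, items)
        k = items.index(("b", 1, 0))
        assert std[k] == pytest.approx(1.0)

    def test_unit_variance_identity(self, regression_model, regression_data):
        """When model-implied variances are 1, beta equals the raw path."""
        fit = fit_ml(regression_model, regression_data)
        std = standardize(fit, regression_model)
        row = std.table.iloc[std.lookup("yl", "xl")]
        k = fit.param_names.index("yl~xl")
        expected = fit.theta_hat[k] * std.latent_sd["xl"] / std.latent_sd["yl"]
        assert row["est_std"] == pytest.approx(expected, rel=1e-10)

    def test_destandardization_roundtrip(self, regression_model,
                                         regression_data):
        fit = fit_ml(regression_model, regression_data)
        std = standardize(fit, regression_model)
        row = std.table.iloc[std.lookup("yl", "xl")]
        raw = row["est_std"] * std.latent_sd["yl"] / std.latent_sd["xl"]
        assert raw == pytest.approx(row["est"], rel=1e-12)

    def test_standardized_loadings_equal_implied_correlations(self):
        """One-factor model: standardized loadings == model-implied
        indicator-factor correlations, cross-checked on a large simulated
        sample's empirical indicator-factor-score correlations."""
        loadings = (0.8, 0.7, 0.6)
        rng = np.random.default_rng(11)
        n = 50000
        f = rng.standard_normal(n)
        y = np.column_stack([
            lam * f + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
            for lam in loadings])
        frame = pd.DataFrame(y, columns=["x1", "x2", "x3"])
        frame["cl"] = np.arange(n)
        data = ClusteredDataset(frame, "cl")
        b = ConceptBinding("f", "reflective", ("x1", "x2", "x3"))
        model = one_factor_model(b)
        fit = fit_ml(model, data)
        std = standardize(fit, model)
        for k, (lam, ind) in enumerate(zip(loadings, ("x1", "x2", "x3"))):
            row = std.table.iloc[std.lookup("f", ind, op="=~")]
            empirical = np.corrcoef(f, y[:, k])[0, 1]
            assert row["est_std"] == pytest.approx(empirical, abs=0.02)
            assert row["est_std"] == pytest.approx(lam, abs=0.02)
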