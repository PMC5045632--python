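"""Score test, dispersion estimate, variance corrections and RLE."""

import numpy as np
import pandas as pd
import pytest

from peremfit import (
    CategoricalSpec,
    estimate_phi,
    fit_perem,
    rle,
    sandwich_variance,
    scale_variance,
    score_test,
)


class TestScoreTest:
    def test_generated_variable_hand_values(self, toy_rate_fit):
        """Observed rates (0.2, 0.4, 0.3) vs fitted 0.3 give
        z = ((lp-0.3)^2 - lp)/0.3 = (-0.6333, -1.3, -1)."""
        st = score_test(toy_rate_fit)
        assert st.per_obs_z == pytest.approx([-0.63333, -1.3, -1.0], abs=1e-5)
        # no-intercept OLS slope: sum(z*0.3) / sum(0.3^2)
        expected_alpha = 0.3 * np.sum([-0.63333, -1.3, -1.0]) / (3 * 0.09)
        assert st.alpha_hat == pytest.approx(expected_alpha, abs=1e-4)
        assert st.alpha_hat < 0  # perfectly Poisson-ish data: under-dispersion direction
        assert st.p_value_one_sided > 0.5

    def test_perfect_fit_gives_z_minus_one(self):
        df = pd.DataFrame({"d": [5, 5, 5], "dstar": [1.0, 1.0, 1.0], "y": [10.0, 10.0, 10.0]})
        fit = fit_perem(df, CategoricalSpec(terms=(), baseline=None))
        st = score_test(fit)
        assert np.allclose(st.per_obs_z, -1.0)
        assert st.alpha_hat < 0

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"d": [3, 5], "dstar": [1.0, 1.0], "y": [10.0, 10.0]})
        fit = fit_perem(df, CategoricalSpec(terms=(), baseline=None))
        with pytest.raises(ValueError, match="3 rows"):
            score_test(fit)

    def test_count_scale_centred_on_grouped_poisson_cells(self):
        """Count-scale z has mean ~0 under a Poisson generating model even
        with heterogeneous person-time, unlike the rate-scale z."""
        rng = np.random.default_rng(42)
        n = 400
        y = rng.uniform(5.0, 200.0, n)
        dstar = 0.01 * y
        lam = 0.08
        d = rng.poisson(dstar + y * lam)
        df = pd.DataFrame({"d": d, "dstar": dstar, "y": y})
        fit = fit_perem(df, CategoricalSpec(terms=(), baseline=None))
        z_count = score_test(fit, scale="count").per_obs_z
        z_rate = score_test(fit, scale="rate").per_obs_z
        assert abs(np.mean(z_count)) < 0.2
        assert np.mean(z_rate) < -0.5  # mis-centred: Var(rate) = mu/y^2 << E(rate)


class TestPhi:
    def test_phi_zero_at_perfect_fit(self):
        df = pd.DataFrame({"d": [5, 5, 5], "dstar": [1.0, 1.0, 1.0], "y": [10.0, 10.0, 10.0]})
        fit = fit_perem(df, CategoricalSpec(terms=(), baseline=None))
        assert estimate_phi(fit).phi == pytest.approx(0.0, abs=1e-12)

    def test_phi_is_chi2_over_df(self, toy_rate_fit):
        est = estimate_phi(toy_rate_fit, "pearson_rate")
        assert est.df == 2
        assert est.phi == pytest.approx(toy_rate_fit.pearson_rate / 2)

    def test_df_zero_rejected(self):
        df = pd.DataFrame({"d": [10], "dstar": [2.0], "y": [100.0]})
        fit = fit_perem(df, CategoricalSpec(terms=(), baseline=None))
        with pytest.raises(ValueError):
            estimate_phi(fit)

    def test_count_phi_near_one_on_large_poisson_data(self):
        rng = np.random.default_rng(9)
        n = 2000
        y = rng.uniform(20.0, 100.0, n)
        dstar = 0.02 * y
        d = rng.poisson(dstar + y * 0.1)
        fit = fit_perem(pd.DataFrame({"d": d, "dstar": dstar, "y": y}),
                        CategoricalSpec(terms=(), baseline=None))
        assert 0.9 <= estimate_phi(fit, "pearson_count").phi <= 1.1

    def test_count_phi_recovers_quasipoisson_dispersion(self):
        """Grouped data with Var(d) = c * mu: phi_hat within 10% of c."""
        rng = np.random.default_rng(17)
        c = 3.0
        n = 3000
        y = rng.uniform(20.0, 100.0, n)
        dstar = 0.02 * y
        mu = dstar + y * 0.1
        # NB1 mixture: Poisson(mu * g), g ~ Gamma(shape=mu/(c-1), scale=(c-1)/mu)
        g = rng.gamma(mu / (c - 1.0), (c - 1.0) / mu)
        d = rng.poisson(mu * g)
        fit = fit_perem(pd.DataFrame({"d": d, "dstar": dstar, "y": y}),
                        CategoricalSpec(terms=(), baseline=None))
        assert estimate_phi(fit, "pearson_count").phi == pytest.approx(c, rel=0.10)


class TestCorrections:
    def test_scale_identity_and_sqrt_phi(self, toy_rate_fit):
        base_se = toy_rate_fit.se
        assert scale_variance(toy_rate_fit, 1.0).se == pytest.approx(base_se)
        assert scale_variance(toy_rate_fit, 4.0).se == pytest.approx(2.0 * base_se)
        with pytest.raises(ValueError):
            scale_variance(toy_rate_fit, 0.0)

    def test_scale_linearity_in_phi(self, toy_rate_fit):
        c1 = scale_variance(toy_rate_fit, 1.3).cov
        c2 = scale_variance(toy_rate_fit, 0.9).cov
        c12 = scale_variance(toy_rate_fit, 2.2).cov
        assert c12 == pytest.approx(c1 + c2)

    def test_published_scaling_arithmetic(self):
        # SE 0.0107 under phi = 21.3 scales to ~0.0494 (printed 0.0493);
        # the robust/base SE pair (0.3159, 0.0465) has variance ratio ~46.15
        assert 0.0107 * np.sqrt(21.3) == pytest.approx(0.0493, abs=6e-4)
        assert (0.3159 / 0.0465) ** 2 == pytest.approx(46.1198, rel=0.002)

    def test_scaled_rle_equals_phi_exactly(self, toy_rate_fit):
        phi = 2.71
        corr = scale_variance(toy_rate_fit, phi)
        assert rle(corr, toy_rate_fit) == pytest.approx(np.full(len(corr.se), phi))

    def test_sandwich_zero_meat_at_perfect_fit(self):
        df = pd.DataFrame({"d": [5, 5, 5], "dstar": [1.0, 1.0, 1.0], "y": [10.0, 10.0, 10.0]})
        fit = fit_perem(df, CategoricalSpec(terms=(), baseline=None))
        for conv in ("paper", "irls"):
            assert np.allclose(sandwich_variance(fit, conv).cov, 0.0, atol=1e-20)

    def test_sandwich_one_parameter_hand_formula(self, toy_rate_fit):
        """Paper convention, intercept only: bread = 1/sum(lp_hat),
        meat = sum((lp - lp_hat)^2)."""
        sw = sandwich_variance(toy_rate_fit, "paper")
        lp_hat = toy_rate_fit.lambda_plus_hat
        lp = toy_rate_fit.lambda_plus_obs
        expected = np.sum((lp - lp_hat) ** 2) / np.sum(lp_hat) ** 2
        assert sw.cov[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_sandwich_with_meat_w_collapses_to_bread(self, toy_rate_fit):
        # replacing the meat by X'WX gives (X'WX)^-1 algebraically
        X = toy_rate_fit.X
        w = toy_rate_fit.lambda_plus_hat
        bread_inv = X.T @ (X * w[:, None])
        bread = np.linalg.inv(bread_inv)
        assert bread @ bread_inv @ bread == pytest.approx(bread)

    def test_irls_sandwich_matches_reference_hc0_when_dstar_zero(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(23)
        n = 60
        df = pd.DataFrame(
            {
                "d": rng.poisson(4.0, n),
                "dstar": 0.0,
                "y": rng.uniform(0.5, 10.0, n),
                "x0": rng.choice(["a", "b"], n),
            }
        )
        spec = CategoricalSpec(terms=("x0",), baseline=None)
        fit = fit_perem(df, spec)
        sw = sandwich_variance(fit, "irls")
        X, _ = spec.design(df)
        glm = sm.GLM(df.d, X, family=sm.families.Poisson(), offset=np.log(df.y)).fit(
            cov_type="HC0"
        )
        assert sw.se == pytest.approx(glm.bse.values, rel=1e-6)

    def test_rle_mismatched_names_rejected(self, toy_rate_fit):
        corr = scale_variance(toy_rate_fit, 2.0)
        corr.names = ["something_else"]
        with pytest.raises(ValueError):
            rle(corr, toy_rate_fit)
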