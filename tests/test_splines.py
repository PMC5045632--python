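"""Restricted cubic spline basis, knot placement, flexible designs."""

import numpy as np
import pandas as pd
import pytest

from peremfit import (
    CategoricalSpec,
    FlexibleSpec,
    KnotSet,
    fit_perem,
    place_knots,
    predict_emrr_over_time,
    rcs_basis,
)
from peremfit.model import DesignError


class TestKnots:
    def test_five_point_symmetric_set(self):
        ks = place_knots([0, 1, 2, 3, 4], n_knots=5)
        assert ks.boundary == (0, 4)
        assert ks.interior == (1, 2, 3)

    def test_identical_times_rejected(self):
        with pytest.raises(ValueError):
            place_knots([2.0] * 10)

    def test_uniform_times_quartiles(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 7, 1000)
        ks = place_knots(t, n_knots=5)
        assert np.asarray(ks.interior) == pytest.approx([1.75, 3.5, 5.25], abs=0.25)

    def test_decreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            KnotSet(boundary=(0, 1), interior=(2,))


class TestBasis:
    KS = KnotSet(boundary=(0.0, 2.0), interior=(1.0,))

    def test_hand_value_at_interior_point(self):
        # lambda = (2-1)/(2-0) = 0.5;
        # z2(1.5) = 0.5^3 - 0.5*1.5^3 - 0.5*(max(1.5-2,0))^3 = -1.5625
        Z = rcs_basis([1.5], self.KS)
        assert Z[0, 0] == pytest.approx(1.5)
        assert Z[0, 1] == pytest.approx(-1.5625, abs=1e-12)

    def test_linear_before_first_knot(self):
        t = np.linspace(-1.0, 0.0, 7)
        Z = rcs_basis(t, self.KS)
        assert np.allclose(Z[:, 1:], 0.0)
        assert Z[:, 0] == pytest.approx(t)

    def test_linear_beyond_boundary_knots_for_random_coefficients(self):
        rng = np.random.default_rng(1)
        ks = place_knots(rng.uniform(0, 7, 200), n_knots=5)
        gamma = rng.normal(size=ks.n_basis + 1)

        def s(t):
            return gamma[0] + rcs_basis(t, ks) @ gamma[1:]

        for grid in (np.linspace(ks.boundary[1] + 0.01, ks.boundary[1] + 3, 50),
                     np.linspace(ks.boundary[0] - 3, ks.boundary[0] - 0.01, 50)):
            second_diff = np.diff(s(grid), 2)
            assert np.max(np.abs(second_diff)) < 1e-8

    def test_c2_continuity_at_knots(self):
        rng = np.random.default_rng(2)
        ks = KnotSet(boundary=(0.0, 7.0), interior=(1.5, 3.0, 5.0))
        gamma = rng.normal(size=ks.n_basis + 1)

        def s(t):
            return gamma[0] + rcs_basis(np.atleast_1d(t), ks) @ gamma[1:]

        # s is an exact cubic on either side of each knot, so a cubic fit to
        # points strictly left/right of the knot recovers the one-sided value
        # and derivatives at the knot to machine precision
        h = 0.05
        for k in ks.all_knots:
            left = np.polynomial.Polynomial.fit(k - h * np.arange(1, 6), s(k - h * np.arange(1, 6)), 3)
            right = np.polynomial.Polynomial.fit(k + h * np.arange(1, 6), s(k + h * np.arange(1, 6)), 3)
            for deriv in range(3):
                lv = left.deriv(deriv)(k) if deriv else left(k)
                rv = right.deriv(deriv)(k) if deriv else right(k)
                assert abs(lv - rv) < 1e-6 * max(1.0, abs(lv))


def _monthly_data(n=400, seed=3):
    """Fine person-interval rows with a smooth declining excess hazard."""
    from peremfit import SimConfig, merge_expected, split_followup
    from peremfit.simulate import simulate_cohort

    cfg = SimConfig(n_subjects=n, smooth_baseline=lambda t: 0.12 * np.exp(-0.3 * t))
    sim = simulate_cohort(cfg, seed=seed)
    months = np.arange(0.0, 7.0 + 1e-9, 1.0 / 12.0)
    return merge_expected(split_followup(sim.cohort, months, restriction=7.0), sim.lifetable), sim


class TestFlexibleDesign:
    def test_column_counts_without_and_with_td_terms(self):
        data, _ = _monthly_data()
        ks = KnotSet(boundary=(0.0, 7.0), interior=(1.0, 2.5, 4.5))
        spec = FlexibleSpec(terms=("ageband", "dep"), knots=ks)
        X, names = spec.design(data)
        # intercept + 4 spline + 4 ageband + 4 dep
        assert X.shape[1] == 1 + 4 + 4 + 4
        spec_td = FlexibleSpec(terms=("ageband", "dep"), knots=ks, td_terms=("dep",))
        X2, names2 = spec_td.design(data)
        assert X2.shape[1] == X.shape[1] + 4 * 4  # 4 levels x 4 basis columns

    def test_unknown_td_term_rejected(self):
        ks = KnotSet(boundary=(0.0, 7.0), interior=(1.0,))
        with pytest.raises(DesignError):
            FlexibleSpec(terms=("dep",), knots=ks, td_terms=("ageband",))

    def test_orthogonalized_fit_reproduces_fitted_values(self):
        data, _ = _monthly_data(n=300)
        ks = KnotSet(boundary=(0.0, 7.0), interior=(1.0, 2.5, 4.5))
        f_raw = fit_perem(data, FlexibleSpec(terms=("dep",), knots=ks))
        f_orth = fit_perem(data, FlexibleSpec(terms=("dep",), knots=ks, orthogonalize=True))
        assert f_orth.mu_hat == pytest.approx(f_raw.mu_hat, rel=1e-6)

    def test_z1_only_design_equals_loglinear_time_fit(self):
        """The basis' first column is t itself, so restricting to z1
        reproduces a log-linear-in-time baseline exactly."""
        data, _ = _monthly_data(n=300)
        ks = KnotSet(boundary=(0.0, 7.0), interior=(3.5,))

        class Z1Spec(FlexibleSpec):
            def design(self, df):
                X, names = FlexibleSpec.design(self, df)
                return X[:, :2], names[:2]  # intercept + z1

        class LinSpec:
            def design(self, df):
                t = (df["tstart"].to_numpy() + df["tstop"].to_numpy()) / 2
                return np.column_stack([np.ones(len(df)), t]), ["(Intercept)", "t"]

        f1 = fit_perem(data, Z1Spec(terms=(), knots=ks))
        f2 = fit_perem(data, LinSpec())
        assert f1.beta == pytest.approx(f2.beta, abs=1e-9)


class TestDispersionReduction:
    def test_flexible_baseline_reduces_misspecification_dispersion(self):
        """A smoothly declining excess hazard fitted with (a) yearly-step
        and (b) spline baselines on identical monthly cells: the step model
        carries within-year lack of fit, so its dispersion estimate must
        exceed the flexible model's."""
        import warnings

        from peremfit import (
            SimConfig,
            collapse,
            estimate_phi,
            merge_expected,
            split_followup,
        )
        from peremfit.simulate import simulate_cohort

        cfg = SimConfig(n_subjects=8000, smooth_baseline=lambda t: 0.5 * np.exp(-1.0 * t))
        sim = simulate_cohort(cfg, seed=9)
        months = np.arange(0.0, 7.0 + 1e-9, 1.0 / 12.0)
        split = merge_expected(
            split_followup(sim.cohort, months, restriction=7.0), sim.lifetable
        )
        cells = collapse(split, by=["ageband", "dep"], exact=False)
        cells["year_int"] = np.floor(cells.tstart + 1e-9).astype(int)
        knots = place_knots(sim.cohort.loc[sim.cohort.status == 1, "time"], 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            coarse = fit_perem(
                cells, CategoricalSpec(terms=("ageband", "dep"), baseline="year_int")
            )
            flex = fit_perem(cells, FlexibleSpec(terms=("ageband", "dep"), knots=knots))
        phi_coarse = estimate_phi(coarse, "pearson_count").phi
        phi_flex = estimate_phi(flex, "pearson_count").phi
        assert phi_flex < phi_coarse


class TestEmrrOverTime:
    def test_identity_contrast_is_one(self):
        data, _ = _monthly_data(n=300)
        ks = KnotSet(boundary=(0.0, 7.0), interior=(1.0, 2.5, 4.5))
        fit = fit_perem(data, FlexibleSpec(terms=("dep",), knots=ks, td_terms=("dep",),
                                           levels={"dep": [1, 2, 3, 4, 5]}))
        curve = predict_emrr_over_time(fit, ({"dep": 3}, {"dep": 3}), np.linspace(0.2, 5, 10))
        assert np.allclose(curve.emrr, 1.0)
        assert np.allclose(curve.se_log, 0.0)

    def test_no_td_terms_gives_constant_emrr(self):
        data, _ = _monthly_data(n=300)
        ks = KnotSet(boundary=(0.0, 7.0), interior=(1.0, 2.5, 4.5))
        fit = fit_perem(data, FlexibleSpec(terms=("dep",), knots=ks,
                                           levels={"dep": [1, 2, 3, 4, 5]}))
        curve = predict_emrr_over_time(fit, ({"dep": 5}, {"dep": 1}), np.linspace(0.2, 5, 10))
        assert np.ptp(curve.emrr.to_numpy()) < 1e-10
        assert not curve.extrapolated.any()

    def test_extrapolation_flagged(self):
        data, _ = _monthly_data(n=300)
        ks = KnotSet(boundary=(0.5, 5.0), interior=(2.0,))
        fit = fit_perem(data, FlexibleSpec(terms=("dep",), knots=ks,
                                           levels={"dep": [1, 2, 3, 4, 5]}))
        curve = predict_emrr_over_time(fit, ({"dep": 5}, {"dep": 1}), [0.1, 3.0, 6.5])
        assert list(curve.extrapolated) == [True, False, True]
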