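import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from surrogacy import (
    DegenerateDesignError,
    InsufficientComparisonsError,
    bootstrap_r2_ci,
    fit_surrogacy,
    loocv_r2,
    slope_test,
)
from conftest import make_dataset


def grid_wls_oracle(x, y, w, a_range, b_range, steps=801):
    """Brute-force weighted least squares: minimize sum w(y - a - bx)^2 on a grid."""
    a = np.linspace(*a_range, steps)
    b = np.linspace(*b_range, steps)
    A, B = np.meshgrid(a, b, indexing="ij")
    sse = np.zeros_like(A)
    for xi, yi, wi in zip(x, y, w):
        sse += wi * (yi - A - B * xi) ** 2
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return a[i], b[j]


class TestFit:
    def test_perfect_collinear_fit(self):
        ds = make_dataset(x=[-0.4, -0.2, 0.1], y=[-0.8, -0.4, 0.2], n=[100, 100, 100])
        fit = fit_surrogacy(ds, "overall")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self, toy_dataset):
        fit = fit_surrogacy(toy_dataset, "overall")
        x, y = fit.x, fit.y
        w = fit.weights_used
        a, b = grid_wls_oracle(
            x, y, w,
            a_range=(fit.intercept - 0.05, fit.intercept + 0.05),
            b_range=(fit.slope - 0.05, fit.slope + 0.05),
        )
        res = 0.1 / 800  # grid resolution
        assert abs(a - fit.intercept) <= res
        assert abs(b - fit.slope) <= res

    def test_r2_equals_squared_weighted_correlation(self, table1):
        for sub, tc in [("overall", "all"), ("male", "ici_alone"), ("female", "ici_chemo")]:
            fit = fit_surrogacy(table1, sub, tc)
            w = fit.weights_used / fit.weights_used.sum()
            xm = np.sum(w * fit.x)
            ym = np.sum(w * fit.y)
            num = np.sum(w * (fit.x - xm) * (fit.y - ym))
            den = math.sqrt(np.sum(w * (fit.x - xm) ** 2) * np.sum(w * (fit.y - ym) ** 2))
            assert fit.r2 == pytest.approx((num / den) ** 2, abs=1e-10)

    def test_weight_rescaling_invariance(self, toy_dataset):
        fit1 = fit_surrogacy(toy_dataset, "overall")
        n_orig = np.round(fit1.weights_used * fit1.mean_n).astype(int)
        scaled = make_dataset(x=fit1.x, y=fit1.y, n=n_orig * 3)
        fit2 = fit_surrogacy(scaled, "overall")
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-10)
        assert fit2.slope == pytest.approx(fit1.slope, abs=1e-10)
        assert fit2.intercept == pytest.approx(fit1.intercept, abs=1e-10)

    @given(c=st.floats(0.2, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_hr_unit_change_metamorphic(self, c):
        """Multiplying all PFS-HRs by c shifts x: R2 and slope unchanged, intercept shifts."""
        ds = make_dataset(
            x=[-0.6, -0.3, -0.1, 0.1], y=[-0.5, -0.35, -0.05, 0.05], n=[300, 500, 250, 400]
        )
        base = fit_surrogacy(ds, "overall")
        n_orig = np.round(base.weights_used * base.mean_n).astype(int)
        shifted = make_dataset(x=base.x + math.log(c), y=base.y, n=n_orig)
        fit = fit_surrogacy(shifted, "overall")
        assert fit.r2 == pytest.approx(base.r2, abs=1e-9)
        assert fit.slope == pytest.approx(base.slope, abs=1e-9)
        assert fit.intercept == pytest.approx(base.intercept - base.slope * math.log(c), abs=1e-8)

    def test_adjusted_with_constant_covariate_reduces_to_unadjusted(self):
        """A constant indicator carries no information: the adjusted fit must
        equal the unadjusted one with partial R^2 = R^2."""
        ds = make_dataset(
            x=[-0.4, -0.2, 0.0, 0.2], y=[-0.3, -0.2, 0.0, 0.1],
            n=[120, 340, 210, 150], tclass=["ici_alone"] * 4,
        )
        unadj = fit_surrogacy(ds, "overall")
        adj = fit_surrogacy(ds, "overall", adjust_for_treatment=True)
        assert adj.slope == pytest.approx(unadj.slope, abs=1e-12)
        assert adj.partial_r2 == pytest.approx(unadj.r2, abs=1e-12)

    def test_partial_r2_identity_with_t_statistic(self, table1):
        """Squared partial correlation equals t^2/(t^2 + df) for the x coefficient."""
        fit = fit_surrogacy(table1, "male", adjust_for_treatment=True)
        t = fit.slope / fit.slope_se
        assert fit.partial_r2 == pytest.approx(t**2 / (t**2 + fit.df_residual), abs=1e-10)

    def test_preconditions(self, table1):
        ds2 = make_dataset(x=[-0.1, 0.1], y=[-0.1, 0.1], n=[100, 100])
        with pytest.raises(InsufficientComparisonsError):
            fit_surrogacy(ds2, "overall")
        flat = make_dataset(x=[0.1, 0.1, 0.1], y=[-0.1, 0.0, 0.1], n=[100] * 3)
        with pytest.raises(DegenerateDesignError):
            fit_surrogacy(flat, "overall")


class TestSlopeTest:
    def test_textbook_formula(self, toy_dataset):
        fit = fit_surrogacy(toy_dataset, "overall")
        # independent evaluation: beta and its SE via explicit matrix algebra
        X = np.column_stack([np.ones_like(fit.x), fit.x])
        W = np.diag(fit.weights_used)
        xtwx_inv = np.linalg.inv(X.T @ W @ X)
        beta = xtwx_inv @ X.T @ W @ fit.y
        resid = fit.y - X @ beta
        s2 = float(resid @ W @ resid) / (len(fit.x) - 2)
        se_b = math.sqrt(s2 * xtwx_inv[1, 1])
        t_exp = beta[1] / se_b
        p_exp = 2 * stats.t.sf(abs(t_exp), len(fit.x) - 2)
        t_stat, p, sig = slope_test(fit)
        assert t_stat == pytest.approx(t_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-12)
        assert sig == (p_exp < 0.05)

    def test_zero_slope_gives_p_one(self):
        ds = make_dataset(x=[-0.3, 0.0, 0.3, 0.0], y=[0.1, -0.1, 0.1, 0.3], n=[100] * 4)
        fit = fit_surrogacy(ds, "overall")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        t_stat, p, sig = slope_test(fit)
        assert p == pytest.approx(1.0, abs=1e-10)
        assert not sig

    def test_perfect_fit_is_significant(self):
        ds = make_dataset(x=[-0.4, -0.2, 0.0, 0.2], y=[-0.4, -0.2, 0.0, 0.2], n=[100] * 4)
        t_stat, p, sig = slope_test(fit_surrogacy(ds, "overall"))
        assert p < 1e-10
        assert sig


class TestBootstrap:
    def test_reproducible_under_seed(self, table1):
        a = bootstrap_r2_ci(table1, "overall", n_boot=200, seed=42)
        b = bootstrap_r2_ci(table1, "overall", n_boot=200, seed=42)
        assert a == b

    def test_seed_changes_interval(self, table1):
        a = bootstrap_r2_ci(table1, "overall", n_boot=200, seed=1)
        b = bootstrap_r2_ci(table1, "overall", n_boot=200, seed=2)
        assert a != b

    def test_degenerate_replicated_points_fail(self):
        ds = make_dataset(x=[0.1, 0.1, 0.1], y=[0.2, 0.2, 0.2], n=[100] * 3)
        with pytest.raises((DegenerateDesignError, RuntimeError)):
            bootstrap_r2_ci(ds, "overall", n_boot=10, seed=0)

    def test_interval_ordered_and_in_unit_range(self, table1):
        lo, hi = bootstrap_r2_ci(table1, "male", n_boot=300, seed=5)
        assert 0.0 <= lo <= hi <= 1.0


class TestLOOCV:
    def test_perfect_linear_data(self):
        ds = make_dataset(
            x=[-0.5, -0.3, -0.1, 0.1, 0.3], y=[-1.0, -0.6, -0.2, 0.2, 0.6], n=[100] * 5
        )
        cv = loocv_r2(ds, "overall")
        assert cv.cv_r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(cv.predictions, cv.observed, atol=1e-10)

    def test_one_prediction_per_comparison_from_heldout_model(self, table1):
        cv = loocv_r2(table1, "male", adjust_for_treatment=True)
        assert len(cv.predictions) == 21
        assert len(set(cv.comparison_ids)) == 21
        # each prediction must differ from the full-model prediction
        # (the held-out point influences the full fit)
        full = fit_surrogacy(table1, "male", adjust_for_treatment=True)
        full_preds = [
            full.predict(x, t) for x, t in zip(full.x, full.treat)
        ]
        assert not np.allclose(cv.predictions, full_preds, atol=1e-12)

    def test_weighted_vs_unweighted_option(self, table1):
        wtd = loocv_r2(table1, "female", "ici_alone")
        unw = loocv_r2(table1, "female", "ici_alone", weighted_correlation=False)
        assert wtd.cv_r2 != pytest.approx(unw.cv_r2, abs=1e-6)
        assert "weighted" in wtd.model_spec
        assert "unweighted" in unw.model_spec

    def test_too_few_comparisons(self):
        ds = make_dataset(x=[-0.3, 0.0, 0.3], y=[-0.2, 0.0, 0.2], n=[100] * 3)
        with pytest.raises(InsufficientComparisonsError):
            loocv_r2(ds, "overall")
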