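"""Agreement statistics: Pearson/Fisher, OLP calibration, SEE, labels.

The OLP closed form is cross-checked against a direct numerical
minimization of the product-of-residuals objective and against pingouin's
independent correlation CI implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from vbtval import (
    OLPRegression,
    bias_flags,
    fisher_ci,
    interpret,
    olp_confidence_limits,
    olp_fit,
    pearson_with_ci,
    see_from_olp,
    three_tier_report,
)
from vbtval.pairing import PairedObservation


def random_xy(rng, n=10):
    x = rng.normal(1.0, 0.3, n)
    y = 0.5 + 0.9 * x + rng.normal(0, 0.2, n)
    return x, y


class TestPearsonFisher:
    def test_perfect_linearity_gives_unit_r_and_degenerate_ci(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, ci = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert ci == (1.0, 1.0)

    def test_null_correlation_interval_width(self):
        """r = 0 at n = 402: the Fisher interval is +/- tanh(1.96/sqrt(399))."""
        lo, hi = fisher_ci(0.0, 402)
        expected = np.tanh(1.959964 / np.sqrt(399))
        assert hi == pytest.approx(expected, abs=1e-6)
        assert hi == pytest.approx(0.098, abs=1e-3)
        assert lo == pytest.approx(-hi)

    def test_agrees_with_pingouin(self, rng):
        import pingouin as pg

        x, y = random_xy(rng, 60)
        r, (lo, hi) = pearson_with_ci(x, y)
        res = pg.corr(x, y)
        assert r == pytest.approx(float(res["r"].iloc[0]), abs=1e-12)
        ci = res["CI95"].iloc[0] if "CI95" in res else res["CI95%"].iloc[0]
        assert lo == pytest.approx(ci[0], abs=5e-3)
        assert hi == pytest.approx(ci[1], abs=5e-3)

    def test_fisher_coverage_at_n100(self):
        """Empirical 95% coverage at rho = 0.9, n = 100 over 1000 draws."""
        rho, n = 0.9, 100
        r = np.random.default_rng(42)
        cov = 0
        for _ in range(1000):
            x = r.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * r.normal(size=n)
            lo, hi = fisher_ci(float(np.corrcoef(x, y)[0, 1]), n)
            cov += lo <= rho <= hi
        assert 930 <= cov <= 970

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2, 3], [1, 2, 3])  # n < 4
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])  # zero variance


class TestOlpFit:
    def test_exact_proportionality(self):
        slope, intercept = olp_fit([1, 2, 3, 4], [2, 4, 6, 8])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_small_case(self):
        """x=[1,2,3], y=[1,3,2]: equal SDs so |slope| = 1; r = 0.5 > 0."""
        x, y = [1, 2, 3, 1, 2, 3], [1, 3, 2, 1, 3, 2]
        slope, intercept = olp_fit(x, y)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_identity_data(self):
        x = np.linspace(0.3, 1.2, 10)
        slope, intercept = olp_fit(x, x)
        see, see_pct = see_from_olp(x, x, slope, intercept)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert see == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_rejected(self):
        x = np.array([1.0, 2.0, 1.0, 2.0])
        y = np.array([1.0, 1.0 + 1e-16, 1.0, 1.0 + 1e-16])
        with pytest.raises(ValueError):
            olp_fit([1, 2, 3, 4], [0, 1, 1, 0])  # r == 0 by symmetry

    def test_matches_numerical_product_minimization(self, rng):
        """Closed form vs direct minimization of sum |dy_i| * |dx_i| on 20
        random datasets."""
        for _ in range(20):
            x, y = random_xy(rng)

            def objective(p):
                a, b = p
                return np.sum((y - a - b * x) ** 2) / abs(b)

            slope, intercept = olp_fit(x, y)
            res = minimize(objective, x0=[0.0, 1.0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
            assert res.x[1] == pytest.approx(slope, abs=1e-6)
            assert res.x[0] == pytest.approx(intercept, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_reciprocity(self, seed):
        """slope(y|x) * slope(x|y) = 1 whenever r != 0."""
        r = np.random.default_rng(seed)
        x, y = random_xy(r, 12)
        s_xy, _ = olp_fit(x, y)
        s_yx, _ = olp_fit(y, x)
        assert s_xy * s_yx == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 5.0), d=st.floats(-2.0, 2.0))
    def test_scale_and_shift_equivariance(self, c, d):
        rng_ = np.random.default_rng(99)
        x, y = random_xy(rng_, 30)
        f0 = OLPRegression().fit(x, y)
        f_scaled = OLPRegression().fit(x, c * y)
        assert f_scaled.slope_ == pytest.approx(c * f0.slope_, rel=1e-9)
        assert f_scaled.see_ == pytest.approx(c * f0.see_, rel=1e-9)
        f_shift = OLPRegression().fit(x, y + d)
        assert f_shift.slope_ == pytest.approx(f0.slope_, rel=1e-9)
        assert f_shift.intercept_ == pytest.approx(f0.intercept_ + d, abs=1e-9)
        assert f_shift.see_ == pytest.approx(f0.see_, rel=1e-9)
        assert f_shift.r_ == pytest.approx(f0.r_, abs=1e-12)


class TestOlpConfidenceLimits:
    def test_perfect_fit_zero_width(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        slope_ci, intercept_ci = olp_confidence_limits(x, 2 * x, 2.0)
        assert slope_ci[0] == pytest.approx(slope_ci[1])
        assert intercept_ci[0] == pytest.approx(intercept_ci[1], abs=1e-9)

    def test_printed_bracket_cross_check(self):
        """Applying the slope-limit formula at (slope 1.022, r 0.976, n 578)
        reproduces the published bracket [1.004, 1.041]."""
        from scipy import stats as sp

        n, r, slope = 578, 0.976, 1.022
        t = sp.t.ppf(0.975, n - 2)
        B = t * t * (1 - r * r) / (n - 2)
        lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
        hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
        assert lo == pytest.approx(1.004, abs=2e-3)
        assert hi == pytest.approx(1.041, abs=2e-3)

    def test_monte_carlo_slope_coverage(self):
        """Empirical 95% slope-CI coverage at n = 50, true slope 1.05, with
        comparable error on both axes (the OLP error model)."""
        rng_ = np.random.default_rng(7)
        true = 1.05
        hit = 0
        n_sim = 600
        for _ in range(n_sim):
            latent = rng_.normal(0.6, 0.2, 50)
            x = latent + rng_.normal(0, 0.05, 50)
            y = -0.02 + true * latent + rng_.normal(0, 0.05 * true, 50)
            f = OLPRegression().fit(x, y)
            hit += f.slope_ci_[0] <= true <= f.slope_ci_[1]
        assert 0.93 * n_sim <= hit <= 0.97 * n_sim


class TestSee:
    def test_estimator_consistency(self):
        rng_ = np.random.default_rng(11)
        x = rng_.uniform(0.3, 1.2, 5000)
        y = x + rng_.normal(0, 0.05, 5000)
        slope, intercept = olp_fit(x, y)
        see, _ = see_from_olp(x, y, slope, intercept)
        assert see == pytest.approx(0.05, abs=0.003)

    def test_percentage_uses_criterion_mean_denominator(self):
        """The published (0.049 m/s, 8.1%) pairing implies a criterion mean
        near 0.605 m/s under the criterion-mean convention."""
        x = np.full(10, 0.605)
        # bypass olp; direct ratio check
        assert 100 * 0.049 / x.mean() == pytest.approx(8.1, abs=0.05)

    def test_perpendicular_variant_is_smaller(self, rng):
        x, y = random_xy(rng, 50)
        slope, intercept = olp_fit(x, y)
        v, _ = see_from_olp(x, y, slope, intercept, "vertical")
        p, _ = see_from_olp(x, y, slope, intercept, "perpendicular")
        assert p < v


class TestInterpretation:
    @pytest.mark.parametrize(
        "slope_ci,intercept_ci,prop,fixed",
        [
            ((1.004, 1.041), (-0.010, 0.012), True, False),
            ((0.95, 1.05), (-0.010, 0.012), False, False),
            ((0.95, 1.05), (0.003, 0.078), False, True),
        ],
    )
    def test_bias_flags(self, slope_ci, intercept_ci, prop, fixed):
        assert bias_flags(slope_ci, intercept_ci) == (prop, fixed)

    @pytest.mark.parametrize(
        "r,see,r_label,p_label",
        [
            (0.976, 0.05, "extremely large", "high"),
            (0.85, 0.188, "very large", "moderate"),
            (0.6, 0.35, "large", "low"),
            (0.3, 0.05, "not large", "high"),
        ],
    )
    def test_labels(self, r, see, r_label, p_label):
        assert interpret(r, see) == (r_label, p_label)


class TestThreeTierReport:
    @staticmethod
    def obs(device, parameter, spectrum, x, y):
        return [
            PairedObservation("S", i, device, parameter, float(yy), float(xx), spectrum)
            for i, (xx, yy) in enumerate(zip(x, y))
        ]

    def test_identity_pairs_everywhere(self):
        x = np.linspace(0.3, 1.2, 12)
        observations = []
        for parameter in ("vmean", "vpeak", "vprop"):
            for spectrum in ("fast", "slow"):
                observations += self.obs("dev", parameter, spectrum, x, x)
        report = three_tier_report(observations)
        est = report[report["estimable"]]
        assert len(est) == 9  # 3 parameters x 3 strata
        assert np.allclose(est["slope"], 1.0)
        assert np.allclose(est["intercept"], 0.0, atol=1e-9)
        assert np.allclose(est["see"], 0.0, atol=1e-9)
        assert np.allclose(est["r"], 1.0)

    def test_report_shape_three_by_three_per_device(self):
        x = np.linspace(0.3, 1.2, 8)
        observations = self.obs("dev", "vmean", "fast", x, x)
        report = three_tier_report(observations)
        assert len(report) == 9
        assert set(report["stratum"]) == {"total", "fast", "slow"}

    def test_small_stratum_reported_not_estimable(self):
        x = np.array([0.5, 0.9])
        observations = self.obs("dev", "vmean", "fast", x, x)
        report = three_tier_report(observations)
        row = report[(report["parameter"] == "vmean") & (report["stratum"] == "fast")]
        assert not row["estimable"].iloc[0]
        assert row["n"].iloc[0] == 2
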