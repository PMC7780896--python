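"""IVW, MR-Egger, SIMEX-corrected Egger, and weighted-median estimators."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from conftest import make_hset, draw_hset
from mrkit.estimators import (
    Method, egger, egger_simex, ivw, weighted_median, _weighted_median_point,
)
from mrkit.simulate import generate, scenario


class TestIVW:
    def test_constant_ratios_recovered_exactly(self):
        g = np.array([0.1, 0.2, 0.4])
        h = make_hset(g, [0.01] * 3, 0.5 * g, [0.1, 0.2, 0.05])
        assert ivw(h).slope == pytest.approx(0.5, abs=1e-14)

    def test_two_snp_closed_form(self):
        # weights (4, 16); slope = (4*0.1 + 16*0.3)/20 = 0.26
        h = make_hset([0.2, 0.4], [0.01, 0.01], [0.02, 0.12], [0.1, 0.1])
        r = ivw(h)
        assert r.slope == pytest.approx(0.26, abs=1e-14)
        assert r.slope_se == pytest.approx(np.sqrt(1 / 20.0), abs=1e-14)

    def test_null_outcome_gives_zero_slope_unit_pvalue(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.1] * 2)
        r = ivw(h)
        assert r.slope == 0.0 and r.slope_pval == pytest.approx(1.0)

    def test_ci_contains_slope(self, simple_hset):
        r = ivw(simple_hset)
        assert r.slope_ci[0] < r.slope < r.slope_ci[1]

    def test_preconditions(self):
        with pytest.raises(ValueError, match="insufficient"):
            ivw(make_hset([0.1], [0.01], [0.0], [0.1]))
        with pytest.raises(ValueError, match="zero exposure effect"):
            ivw(make_hset([0.0, 0.1], [0.01] * 2, [0, 0], [0.1] * 2))


class TestEgger:
    def test_exact_line_interpolated(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(g, [0.01] * 4, 0.02 + 0.4 * g, [0.1] * 4)
        r = egger(h)
        assert r.intercept == pytest.approx(0.02, abs=1e-12)
        assert r.slope == pytest.approx(0.4, abs=1e-12)

    def test_constant_outcome_gives_zero_slope(self):
        g = np.array([0.1, 0.2, 0.3])
        h = make_hset(g, [0.01] * 3, [0.07] * 3, [0.1] * 3)
        r = egger(h)
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.intercept == pytest.approx(0.07, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(11)
        g = rng.uniform(0.05, 0.4, 5)
        sy = rng.uniform(0.05, 0.3, 5)
        a = 0.01 + 0.3 * g + rng.normal(0, 0.05, 5)
        h = make_hset(g, [0.01] * 5, a, sy)
        r = egger(h)
        fit = sm.WLS(a, sm.add_constant(g), weights=1 / sy**2).fit()
        assert r.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert r.slope == pytest.approx(fit.params[1], abs=1e-10)
        # model-based (fixed-dispersion) covariance
        cov = np.linalg.inv(fit.model.exog.T @ (np.diag(1 / sy**2) @ fit.model.exog))
        assert r.slope_se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="insufficient"):
            egger(make_hset([0.1, 0.2], [0.01] * 2, [0, 0], [0.1] * 2))
        with pytest.raises(ValueError, match="degenerate"):
            egger(make_hset([0.2, 0.2, -0.2], [0.01] * 3, [0, 0, 0], [0.1] * 3))


class TestSimex:
    def test_no_measurement_error_reduces_to_egger(self, simple_hset):
        h = make_hset(simple_hset.gamma_hat, [1.0] * 6,
                      simple_hset.alpha_hat, simple_hset.sigma_y)
        # exactly-zero exposure SE is the error-free edge case; bypass the
        # container's positivity check to exercise it
        h.sigma_x = np.zeros(6)
        naive = egger(h)
        for grid in [(0.0, 1.0, 2.0), (0.0, 0.25, 0.5, 0.75)]:
            r = egger_simex(h, lambda_grid=grid, b_reps=150, seed=1)
            assert r.method is Method.EGGER_SIMEX
            assert r.slope == naive.slope and r.intercept == naive.intercept
            assert r.slope_se == naive.slope_se

    def test_requires_replicates_and_zero_lambda(self, simple_hset):
        with pytest.raises(ValueError, match="replicates"):
            egger_simex(simple_hset, b_reps=99)
        with pytest.raises(ValueError, match="lambda"):
            egger_simex(simple_hset, lambda_grid=(0.5, 1.0))

    def test_corrects_attenuation_on_average(self):
        # I2_GX ~ 0.7 regime: naive Egger slope is diluted toward zero
        n_rep, truth = 60, 0.3
        naive_err, simex_err = [], []
        for i in range(n_rep):
            h = draw_hset("nome_violated", seed=50_000 + i)
            naive_err.append(egger(h).slope - truth)
            simex_err.append(egger_simex(h, b_reps=100, seed=i).slope - truth)
        assert abs(np.mean(simex_err)) < abs(np.mean(naive_err))
        assert np.mean(naive_err) < 0  # attenuation toward zero


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        g = np.array([0.1, 0.1, 0.1])
        h = make_hset(g, [0.01] * 3, g * np.array([0.1, 0.5, 0.9]), [0.1] * 3)
        assert weighted_median(h, n_boot=100, seed=0).slope == pytest.approx(0.5)

    def test_dominant_instrument_returns_its_ratio(self):
        # weights 0.1/0.8/0.1: the dominant instrument's mass interval is
        # centred on 1/2, so the interpolated median is exactly its ratio
        g = np.array([0.1, 0.1, 0.1])
        sy = np.array([np.sqrt(1 / 0.1), np.sqrt(1 / 0.8), np.sqrt(1 / 0.1)]) * 0.1
        h = make_hset(g, [0.01] * 3, g * np.array([0.1, 0.5, 0.9]), sy)
        assert weighted_median(h, n_boot=100, seed=0).slope == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_interpolation(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0.1, 0.4, 4)
        sy = rng.uniform(0.05, 0.2, 4)
        a = rng.normal(0.1, 0.1, 4)
        ratios = a / g
        weights = g**2 / sy**2

        # independent brute-force evaluation of the definition
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order] / weights.sum()
        s = np.cumsum(w)
        p = s - w / 2
        k = int(np.searchsorted(p, 0.5))
        expected = r[k - 1] + (r[k] - r[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1])

        est = _weighted_median_point(ratios, weights)
        assert est == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_is_deterministic_per_seed(self, simple_hset):
        a = weighted_median(simple_hset, n_boot=200, seed=42)
        b = weighted_median(simple_hset, n_boot=200, seed=42)
        assert a.slope_se == b.slope_se

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_estimate_bounded_by_extreme_ratios(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(3, 10))
        g = rng.uniform(0.05, 0.5, j)
        h = make_hset(g, rng.uniform(0.001, 0.01, j),
                      rng.normal(0, 0.1, j), rng.uniform(0.05, 0.3, j))
        ratios = h.alpha_hat / h.gamma_hat
        est = weighted_median(h, n_boot=100, seed=0).slope
        assert ratios.min() - 1e-12 <= est <= ratios.max() + 1e-12


class TestSharedProperties:
    def test_scale_equivariance_in_outcome_units(self, simple_hset):
        c = 2.5
        scaled = make_hset(simple_hset.gamma_hat, simple_hset.sigma_x,
                           c * simple_hset.alpha_hat, c * simple_hset.sigma_y)
        assert ivw(scaled).slope == pytest.approx(c * ivw(simple_hset).slope)
        assert egger(scaled).slope == pytest.approx(c * egger(simple_hset).slope)
        assert weighted_median(scaled, 100, 0).slope == pytest.approx(
            c * weighted_median(simple_hset, 100, 0).slope)
        assert egger_simex(scaled, b_reps=150, seed=3).slope == pytest.approx(
            c * egger_simex(simple_hset, b_reps=150, seed=3).slope)

    def test_orientation_invariance(self, simple_hset):
        flip = np.array([1, -1, 1, -1, -1, 1.0])
        flipped = make_hset(flip * simple_hset.gamma_hat, simple_hset.sigma_x,
                            flip * simple_hset.alpha_hat, simple_hset.sigma_y)
        assert ivw(flipped).slope == pytest.approx(ivw(simple_hset).slope, abs=1e-14)
        assert egger(flipped).slope == pytest.approx(egger(simple_hset).slope, abs=1e-14)
        assert weighted_median(flipped, 100, 0).slope == pytest.approx(
            weighted_median(simple_hset, 100, 0).slope, abs=1e-14)

    def test_egger_through_origin_equals_ivw(self, simple_hset):
        # zero-intercept WLS slope == IVW slope (algebraic identity)
        w = 1 / simple_hset.sigma_y**2
        g, a = simple_hset.gamma_hat, simple_hset.alpha_hat
        slope_origin = np.sum(w * g * a) / np.sum(w * g * g)
        assert ivw(simple_hset).slope == pytest.approx(slope_origin, abs=1e-10)


def test_weighted_median_breakdown_resists_forty_percent_invalid():
    """With 40% of instruments carrying strong directional pleiotropy, the
    weighted median stays closer to the truth than IVW on average."""
    truth = 0.2
    base = scenario("valid_causal")
    from dataclasses import replace
    from mrkit.simulate import GammaLaw
    cfg0 = replace(base, frac_invalid=0.4, pleiotropy_mean=0.15,
                   pleiotropy_sd=0.02, gamma_law=GammaLaw(random_sign=False))
    ivw_err, wm_err = [], []
    for i in range(500):
        from mrkit.sumstats import harmonize
        exp, out, _ = generate(replace(cfg0, seed=20_000 + i))
        h = harmonize(exp, out)
        ivw_err.append(ivw(h).slope - truth)
        wm_err.append(_weighted_median_point(h.alpha_hat / h.gamma_hat,
                                             h.gamma_hat**2 / h.sigma_y**2))
    wm_err = np.asarray(wm_err) - truth
    assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err))
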