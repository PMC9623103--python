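"""Causal estimators against independent oracles and their invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tsmr import estimators as est
from tsmr.exceptions import InsufficientInstrumentsError, ValidationError

from conftest import make_instruments, random_instruments


def wls_origin_slope(ins):
    """Independent oracle: origin-constrained WLS of beta_out on beta_exp."""
    fit = sm.WLS(ins["beta_out"], ins[["beta_exp"]], weights=ins["se_out"] ** -2).fit()
    return float(fit.params.iloc[0])


def wls_egger(ins):
    """Independent oracle: weighted regression with intercept on oriented betas."""
    flip = np.sign(ins["beta_exp"].to_numpy())
    x = ins["beta_exp"].to_numpy() * flip
    y = ins["beta_out"].to_numpy() * flip
    fit = sm.WLS(y, sm.add_constant(x), weights=ins["se_out"].to_numpy() ** -2.0).fit()
    return float(fit.params[0]), float(fit.params[1])


def weighted_median_scan(ratios, weights, n_grid=2_000_001):
    """Independent oracle: brute-force scan of the interpolated weighted
    percentile function over a dense grid."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    # breakpoints of the percentile function, built by explicit accumulation
    s = []
    acc = 0.0
    for wj in w:
        s.append(acc + wj / 2)
        acc += wj
    s = np.array(s) / acc
    grid = np.linspace(r[0], r[-1], n_grid)
    sq = np.interp(grid, r, s)
    return float(grid[np.argmin(np.abs(sq - 0.5))])


class TestWaldRatio:
    def test_closed_form(self):
        r = est.wald_ratio({"snp_id": "rs1", "beta_exp": 0.5, "beta_out": 0.25, "se_out": 0.1})
        assert r.ratio == pytest.approx(0.5)
        assert r.se_ratio == pytest.approx(0.2)
        assert r.weight == pytest.approx(0.2**-2)

    def test_null_numerator(self):
        assert est.wald_ratio({"beta_exp": 0.5, "beta_out": 0.0, "se_out": 0.1}).ratio == 0

    def test_sign_cancellation(self):
        a = est.wald_ratio({"beta_exp": 0.5, "beta_out": 0.25, "se_out": 0.1})
        b = est.wald_ratio({"beta_exp": -0.5, "beta_out": -0.25, "se_out": 0.1})
        assert a.ratio == b.ratio and a.se_ratio == b.se_ratio

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError):
            est.wald_ratio({"beta_exp": 0.0, "beta_out": 0.1, "se_out": 0.1})


class TestIVW:
    def test_degenerate_heterogeneity_returns_common_ratio(self):
        ins = make_instruments([0.1, 0.2, 0.4], [0.01] * 3,
                               [0.05, 0.10, 0.20], [0.01, 0.02, 0.01])
        fixed = est.ivw(ins, model="fixed")
        random = est.ivw(ins, model="random")
        assert fixed.beta == pytest.approx(0.5)
        assert random.beta == pytest.approx(0.5)
        assert random.se == pytest.approx(fixed.se)  # Q = 0, clamp at 1

    def test_three_instrument_toy_matches_wls_oracle(self):
        ins = make_instruments([0.1, 0.2, 0.4], [0.01] * 3,
                               [0.03, 0.02, 0.12], [0.01, 0.02, 0.01])
        assert est.ivw(ins, model="fixed").beta == pytest.approx(
            wls_origin_slope(ins), rel=1e-10
        )

    def test_single_instrument_rejected(self):
        ins = make_instruments([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            est.ivw(ins)

    def test_auto_switches_on_heterogeneity(self, rng):
        homogeneous = make_instruments([0.1, 0.2, 0.4], [0.01] * 3,
                                       [0.05, 0.10, 0.20], [0.01] * 3)
        assert est.ivw(homogeneous, model="auto").method == "ivw-fixed"
        heterogeneous = make_instruments([0.1, 0.2, 0.4], [0.01] * 3,
                                         [0.15, -0.1, 0.3], [0.01] * 3)
        assert est.ivw(heterogeneous, model="auto").method == "ivw-random"

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            ins = random_instruments(rng)
            assert est.ivw(ins, model="random").se >= est.ivw(ins, model="fixed").se


class TestEgger:
    def test_exact_line_through_origin_gives_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        ins = make_instruments(bx, [0.01] * 4, 0.7 * bx, [0.01, 0.02, 0.03, 0.01])
        res = est.egger(ins)
        assert res.intercept == pytest.approx(0.0, abs=1e-14)
        assert res.slope.beta == pytest.approx(0.7, rel=1e-12)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        ins = random_instruments(rng, J=6)
        icept, slope = wls_egger(ins)
        res = est.egger(ins)
        assert res.intercept == pytest.approx(icept, rel=1e-10, abs=1e-14)
        assert res.slope.beta == pytest.approx(slope, rel=1e-10)

    def test_too_few_instruments_rejected(self):
        ins = make_instruments([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            est.egger(ins)

    def test_reduces_to_ivw_with_intercept_constrained(self, rng):
        """The origin-constrained version of the Egger fit is exactly IVW."""
        for _ in range(10):
            ins = random_instruments(rng)
            assert wls_origin_slope(ins) == pytest.approx(
                est.ivw(ins, model="fixed").beta, rel=1e-10
            )


class TestWeightedMedian:
    def test_symmetric_equal_weight_ratios(self):
        ins = make_instruments([0.1, 0.1, 0.1], [0.01] * 3,
                               [0.04, 0.05, 0.06], [0.01] * 3)
        assert est.weighted_median(ins, n_boot=100, seed=1).beta == pytest.approx(0.5)

    def test_matches_percentile_scan_oracle(self, rng):
        for _ in range(10):
            ins = random_instruments(rng)
            ratios = (ins["beta_out"] / ins["beta_exp"]).to_numpy()
            weights = (ins["beta_exp"] / ins["se_out"]).to_numpy() ** 2
            span = ratios.max() - ratios.min()
            expected = weighted_median_scan(ratios, weights)
            got = est.weighted_median(ins, n_boot=100, seed=2).beta
            assert abs(got - expected) <= span * 1e-5

    def test_equal_weights_equal_unweighted_median(self):
        ratios = np.array([0.2, 0.9, 0.4, 0.6, 0.1])
        ins = make_instruments(np.full(5, 0.1), [0.01] * 5, 0.1 * ratios, [0.01] * 5)
        assert est.weighted_median(ins, n_boot=100, seed=3).beta == pytest.approx(
            np.median(ratios)
        )

    def test_small_bootstrap_warns(self):
        ins = make_instruments([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.14], [0.01] * 3)
        with pytest.warns(UserWarning, match="n_boot"):
            est.weighted_median(ins, n_boot=50, seed=4)


class TestWeightedMode:
    def test_point_mass_returns_common_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        ins = make_instruments(bx, [0.01] * 3, 0.3 * bx, [0.01] * 3)
        assert est.weighted_mode(ins, n_boot=100, seed=5).beta == pytest.approx(0.3)

    def test_bimodal_toy_finds_heavy_cluster(self):
        # 5 tight, precisely measured ratios near 0.5; 2 noisy ones near 2.0
        bx = np.array([0.2] * 5 + [0.2] * 2)
        ratios = np.array([0.48, 0.49, 0.5, 0.51, 0.52, 1.9, 2.1])
        sy = np.array([0.005] * 5 + [0.1] * 2)
        ins = make_instruments(bx, [0.01] * 7, ratios * bx, sy)
        got = est.weighted_mode(ins, n_boot=100, seed=6).beta
        assert 0.4 < got < 0.6
        # independent dense-grid density maximization
        w = (bx / sy) ** 2
        sd = np.std(ratios, ddof=1)
        iqr = np.percentile(ratios, 75) - np.percentile(ratios, 25)
        h = 0.9 * min(sd, iqr / 1.34) * 7 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2001)
        dens = np.array([np.sum(w * np.exp(-0.5 * ((g - ratios) / h) ** 2)) for g in grid])
        assert got == pytest.approx(grid[np.argmax(dens)], abs=1e-12)

    def test_mode_bounded_by_ratio_range_under_bandwidth_doubling(self, rng):
        ins = random_instruments(rng)
        ratios = (ins["beta_out"] / ins["beta_exp"]).to_numpy()
        for phi in (0.5, 1.0, 2.0, 4.0):
            got = est.weighted_mode(ins, phi=phi, n_boot=100, seed=7).beta
            assert ratios.min() <= got <= ratios.max()


class TestSharedInvariances:
    def _all_betas(self, ins):
        return np.array(
            [
                est.ivw(ins, model="fixed").beta,
                est.ivw(ins, model="random").beta,
                est.egger(ins).slope.beta,
                est.weighted_median(ins, n_boot=100, seed=8).beta,
                est.weighted_mode(ins, n_boot=100, seed=8).beta,
            ]
        )

    def test_scale_equivariance(self, rng):
        """Scaling outcome betas and SEs by k scales every estimate by k."""
        ins = random_instruments(rng)
        k = 2.5
        scaled = ins.copy()
        scaled["beta_out"] *= k
        scaled["se_out"] *= k
        np.testing.assert_allclose(self._all_betas(scaled), k * self._all_betas(ins),
                                   rtol=1e-9)

    def test_instrument_orientation_invariance(self, rng):
        """Negating one instrument's exposure and outcome betas changes nothing."""
        ins = random_instruments(rng)
        flipped = ins.copy()
        flipped.loc[2, ["beta_exp", "beta_out"]] *= -1
        np.testing.assert_allclose(self._all_betas(flipped), self._all_betas(ins),
                                   rtol=1e-12)

    def test_or_scale_is_exponentiated_beta(self, rng):
        ins = random_instruments(rng)
        e = est.ivw(ins, model="fixed")
        assert e.or_ == pytest.approx(np.exp(e.beta))
        assert e.ci_low <= e.beta <= e.ci_high
        assert 0 < e.pval <= 1
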