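"""Causal estimators: closed-form toys, independent weighted-regression
oracles, robustness on synthetic truth, and invariance properties."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import merge_two_sample, pairs_frame
from mrscan.errors import InsufficientInstrumentsError, ValidationError
from mrscan.estimators import (
    cochran_q,
    diagnostics_data,
    ivw_fixed,
    leave_one_out,
    mr_egger,
    to_or,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrscan.synthetic import SimulationScenario, simulate_two_sample


def random_pairs(rng, k=20):
    bx = rng.uniform(0.02, 0.3, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.005, 0.05, k)
    by = rng.normal(0.3 * bx, 0.05)
    sy = rng.uniform(0.01, 0.1, k)
    return pairs_frame(bx, sx, by, sy)


class TestWaldRatio:
    def test_unit_denominator(self):
        res = wald_ratio({"beta_exposure": 1.0, "beta_outcome": 0.5,
                          "se_outcome": 0.1})
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_hand_evaluated_negative_denominator(self):
        res = wald_ratio({"beta_exposure": -0.2, "beta_outcome": 0.1,
                          "se_outcome": 0.05})
        assert res.beta == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.25)

    def test_zero_exposure_effect_undefined(self):
        with pytest.raises(ValidationError):
            wald_ratio({"beta_exposure": 0.0, "beta_outcome": 0.1,
                        "se_outcome": 0.05})


class TestIvwFixed:
    def test_single_pair_equals_wald(self):
        pairs = pairs_frame([0.3], [0.02], [0.15], [0.04])
        ivw = ivw_fixed(pairs)
        wald = wald_ratio(pairs.iloc[0])
        assert ivw.beta == wald.beta
        assert ivw.se == wald.se

    def test_symmetric_toy_closed_form(self):
        pairs = pairs_frame([1, 1, 1], [0.01] * 3, [0.5] * 3, [0.1] * 3)
        res = ivw_fixed(pairs)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / math.sqrt(3))

    def test_matches_origin_constrained_wls_oracle(self, rng):
        for _ in range(20):
            pairs = random_pairs(rng)
            res = ivw_fixed(pairs)
            fit = sm.WLS(
                pairs["beta_outcome"], pairs[["beta_exposure"]],
                weights=1.0 / pairs["se_outcome"] ** 2,
            ).fit()
            assert res.beta == pytest.approx(fit.params.iloc[0], abs=1e-10)
            # fixed-effect SE: unit residual scale
            assert res.se == pytest.approx(
                fit.bse.iloc[0] / math.sqrt(fit.scale), abs=1e-10
            )

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed(pairs_frame([], [], [], []))


class TestMrEgger:
    def test_exact_interpolation_toy(self):
        bx = np.array([1.0, 2.0, 3.0])
        by = 0.1 + 0.4 * bx
        res = mr_egger(pairs_frame(bx, [0.01] * 3, by, [0.1, 0.2, 0.15]))
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-12)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(20):
            pairs = random_pairs(rng)
            res = mr_egger(pairs)
            # oracle orients bXG >= 0 the same way
            sgn = np.sign(pairs["beta_exposure"].to_numpy())
            bx = pairs["beta_exposure"].to_numpy() * sgn
            by = pairs["beta_outcome"].to_numpy() * sgn
            w = 1.0 / pairs["se_outcome"].to_numpy() ** 2
            fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
            assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
            unscaled = fit.bse / math.sqrt(fit.scale)
            phi = math.sqrt(max(1.0, fit.scale))
            assert res.egger_intercept_se == pytest.approx(
                unscaled[0] * phi, abs=1e-10
            )
            assert res.se == pytest.approx(unscaled[1] * phi, abs=1e-10)

    def test_recovers_directional_pleiotropy_mean(self):
        # instruments at post-selection strength so the bXG >= 0 orientation
        # is stable (weak SNPs with misjudged signs attenuate the intercept)
        ests = []
        for seed in range(40):
            scen = SimulationScenario(
                n_instrument_snps=50, n_null_snps=0, theta=0.2,
                exposure_effect_sd=0.1, pleiotropy_model="directional",
                pleiotropy_mean=0.05, pleiotropy_sd=0.02,
                n_exposure=200_000, n_outcome=200_000, seed=100 + seed,
            )
            ex, out, _ = simulate_two_sample(scen)
            ests.append(mr_egger(merge_two_sample(ex, out)).egger_intercept)
        assert np.mean(ests) == pytest.approx(0.05, abs=0.01)

    def test_too_few_or_collinear(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(pairs_frame([1, 2], [0.01] * 2, [0.5, 0.9], [0.1] * 2))
        with pytest.raises(ValidationError):
            mr_egger(pairs_frame([1, 1, 1], [0.01] * 3, [0.4, 0.5, 0.6],
                                 [0.1] * 3))


def brute_force_weighted_median(r, w):
    """Cumulative-weight oracle: weighted 50th percentile with linear
    interpolation over midpoints, computed step by step."""
    order = np.argsort(r)
    r = np.asarray(r, dtype=float)[order]
    w = np.asarray(w, dtype=float)[order]
    w = w / w.sum()
    mid = []
    acc = 0.0
    for wi in w:
        mid.append(acc + wi / 2.0)
        acc += wi
    mid = np.array(mid)
    if 0.5 <= mid[0]:
        return r[0]
    if 0.5 >= mid[-1]:
        return r[-1]
    j = np.searchsorted(mid, 0.5)
    frac = (0.5 - mid[j - 1]) / (mid[j] - mid[j - 1])
    return r[j - 1] + frac * (r[j] - r[j - 1])


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        pairs = pairs_frame([1, 1, 1], [1e-9] * 3, [0.4, 0.5, 0.6], [0.1] * 3)
        res = weighted_median(pairs, n_boot=16, seed=0)
        assert res.beta == pytest.approx(0.5, abs=1e-9)

    def test_interpolated_value_matches_cumulative_oracle(self):
        # ratios (0,1,2,3), weights (0.4,0.1,0.1,0.4) -> 1.5
        from mrscan.estimators import _weighted_median

        r = np.array([0.0, 1.0, 2.0, 3.0])
        w = np.array([0.4, 0.1, 0.1, 0.4])
        assert _weighted_median(r, w) == pytest.approx(
            brute_force_weighted_median(r, w), abs=1e-12
        )
        assert _weighted_median(r, w) == pytest.approx(1.5)

    def test_random_instances_match_oracle(self, rng):
        from mrscan.estimators import _weighted_median

        for _ in range(50):
            k = rng.integers(3, 30)
            r = rng.normal(size=k)
            w = rng.uniform(0.1, 1.0, size=k)
            assert _weighted_median(r, w) == pytest.approx(
                brute_force_weighted_median(r, w), abs=1e-12
            )

    def test_resists_invalid_minority_where_ivw_fails(self):
        bias_ivw, bias_med = [], []
        for seed in range(30):
            scen = SimulationScenario(
                n_instrument_snps=50, n_null_snps=0, theta=0.2,
                pleiotropy_model="directional", pleiotropy_mean=0.1,
                pleiotropy_sd=0.02, pleiotropy_fraction=0.4,
                n_exposure=50_000, n_outcome=50_000, seed=700 + seed,
            )
            ex, out, _ = simulate_two_sample(scen)
            pairs = merge_two_sample(ex, out)
            bias_ivw.append(ivw_fixed(pairs).beta - 0.2)
            bias_med.append(
                weighted_median(pairs, n_boot=8, seed=seed).beta - 0.2
            )
        assert abs(np.median(bias_med)) < 0.5 * abs(np.median(bias_ivw))

    def test_bootstrap_se_deterministic_under_seed(self):
        pairs = pairs_frame([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.11, 0.14],
                            [0.02] * 3)
        a = weighted_median(pairs, n_boot=64, seed=7)
        b = weighted_median(pairs, n_boot=64, seed=7)
        assert a.se == b.se


def grid_mode_oracle(r, w, h):
    grid = np.linspace(min(r) - 3 * h, max(r) + 3 * h, 20001)
    dens = np.array([np.sum(w * np.exp(-0.5 * ((x - r) / h) ** 2)) for x in grid])
    return grid[np.argmax(dens)]


class TestWeightedMode:
    def test_identical_ratios_degenerate(self):
        pairs = pairs_frame([1, 1, 1, 1], [1e-9] * 4, [0.7] * 4, [0.1] * 4)
        res = weighted_mode(pairs, n_boot=8, seed=0)
        assert res.beta == pytest.approx(0.7, abs=1e-12)

    def test_majority_cluster_found(self):
        from mrscan.estimators import _mode_bandwidth, _weighted_mode

        r = np.array([0.2] * 7 + [1.0, 1.02, 0.98])
        r = r + np.linspace(-0.01, 0.01, 10)  # break exact ties
        w = np.full(10, 0.1)
        est = _weighted_mode(r, w, 1.0)
        h = _mode_bandwidth(r, 1.0)
        assert est == pytest.approx(grid_mode_oracle(r, w, h), abs=1e-3)
        assert abs(est - 0.2) < 0.1

    def test_recovers_theta_with_valid_majority(self):
        ests = []
        for seed in range(20):
            scen = SimulationScenario(
                n_instrument_snps=60, n_null_snps=0, theta=0.2,
                pleiotropy_model="directional", pleiotropy_mean=0.15,
                pleiotropy_sd=0.02, pleiotropy_fraction=0.3,
                n_exposure=100_000, n_outcome=100_000, seed=900 + seed,
            )
            ex, out, _ = simulate_two_sample(scen)
            ests.append(
                weighted_mode(merge_two_sample(ex, out), n_boot=8,
                              seed=seed).beta
            )
        assert np.median(ests) == pytest.approx(0.2, abs=0.05)


class TestCochranQ:
    def test_no_dispersion(self):
        pairs = pairs_frame([1, 2], [0.01] * 2, [0.5, 1.0], [0.1] * 2)
        q, df, p, i2 = cochran_q(pairs, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1 and i2 == 0.0

    def test_hand_evaluated_two_pair_toy(self):
        # ratios 0 and 1 with unit weights (bx=1, sy=1): Q about 0.5 is 0.5
        pairs = pairs_frame([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])
        q, df, p, i2 = cochran_q(pairs, 0.5)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_null_simulation_q_mean_near_df(self):
        qs = []
        for seed in range(60):
            scen = SimulationScenario(
                n_instrument_snps=20, n_null_snps=0, theta=0.3,
                n_exposure=200_000, n_outcome=200_000, seed=1000 + seed,
            )
            ex, out, _ = simulate_two_sample(scen)
            pairs = merge_two_sample(ex, out)
            qs.append(cochran_q(pairs, ivw_fixed(pairs).beta)[0])
        assert np.mean(qs) == pytest.approx(19, rel=0.15)


class TestLeaveOneOut:
    def test_length_and_labels(self):
        pairs = pairs_frame([0.1, 0.2, 0.3, 0.4], [0.01] * 4,
                            [0.05, 0.1, 0.15, 0.2], [0.02] * 4)
        results = leave_one_out(pairs)
        assert len(results) == 4
        assert [r.label for r in results] == pairs["rsid"].tolist()

    def test_homogeneous_toy_all_equal(self):
        pairs = pairs_frame([0.2] * 5, [0.01] * 5, [0.1] * 5, [0.02] * 5)
        full = ivw_fixed(pairs).beta
        for res in leave_one_out(pairs):
            assert res.beta == pytest.approx(full, abs=1e-14)

    def test_outlier_omission_moves_estimate_most(self):
        bx = [0.2] * 6 + [0.2]
        by = [0.1] * 6 + [0.5]  # one gross outlier
        pairs = pairs_frame(bx, [0.01] * 7, by, [0.02] * 7)
        full = ivw_fixed(pairs).beta
        shifts = [abs(r.beta - full) for r in leave_one_out(pairs)]
        assert int(np.argmax(shifts)) == 6


class TestToOr:
    def test_null_point(self):
        or_v, lo, hi, p = to_or(0.0, 0.1)
        assert or_v == 1.0 and p == 1.0
        assert lo < 1.0 < hi

    def test_hand_evaluated_log2(self):
        or_v, lo, hi, p = to_or(math.log(2), 0.1)
        assert or_v == pytest.approx(2.0)
        assert lo == pytest.approx(math.exp(math.log(2) - 1.95996 * 0.1), rel=1e-4)
        assert hi == pytest.approx(math.exp(math.log(2) + 1.95996 * 0.1), rel=1e-4)

    def test_ci_brackets_or(self, rng):
        for _ in range(20):
            beta, se = rng.normal(), rng.uniform(0.01, 1)
            or_v, lo, hi, p = to_or(beta, se)
            assert lo <= or_v <= hi
            assert or_v == pytest.approx(math.exp(beta))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            to_or(0.1, 0.0)


class TestInvariances:
    def test_scale_equivariance_of_all_methods(self, rng):
        pairs = random_pairs(rng, k=12)
        c = 3.7
        scaled = pairs.copy()
        scaled["beta_outcome"] *= c
        scaled["se_outcome"] *= c
        for fn in (ivw_fixed, mr_egger,
                   lambda p: weighted_median(p, n_boot=32, seed=5),
                   lambda p: weighted_mode(p, n_boot=32, seed=5)):
            a, b = fn(pairs), fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-6)
            assert b.se == pytest.approx(c * a.se, rel=1e-6)

    def test_orientation_invariance(self, rng):
        pairs = random_pairs(rng, k=10)
        flipped = pairs.copy()
        sel = [0, 3, 7]
        flipped.loc[sel, "beta_exposure"] *= -1
        flipped.loc[sel, "beta_outcome"] *= -1
        for fn in (ivw_fixed, mr_egger,
                   lambda p: weighted_median(p, n_boot=16, seed=3)):
            assert fn(flipped).beta == pytest.approx(fn(pairs).beta, rel=1e-9)


class TestDiagnostics:
    def test_tables_shapes_and_lines(self, rng):
        pairs = random_pairs(rng, k=9)
        results = {"ivw": ivw_fixed(pairs), "egger": mr_egger(pairs)}
        scatter, funnel = diagnostics_data(pairs, results)
        assert len(scatter) == 9 and len(funnel) == 9
        assert (funnel["precision"] > 0).all()
        lines = scatter.attrs["lines"]
        assert set(lines["method"]) == {"ivw_fixed", "mr_egger"}
        assert set(funnel.attrs["verticals"]) == {"ivw_fixed", "mr_egger"}

    def test_null_funnel_roughly_symmetric(self):
        ratios = []
        scen = SimulationScenario(
            n_instrument_snps=400, n_null_snps=0, theta=0.0,
            n_exposure=200_000, n_outcome=200_000, seed=77,
        )
        ex, out, _ = simulate_two_sample(scen)
        pairs = merge_two_sample(ex, out)
        _, funnel = diagnostics_data(pairs, [ivw_fixed(pairs)])
        # regression of ratio on 1/precision should be flat under the null
        slope = np.polyfit(1.0 / funnel["precision"], funnel["ratio"], 1)[0]
        assert abs(slope) < 2.0
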