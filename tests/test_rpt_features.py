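"""Feature-extraction correctness: entropy/K/sigma worked examples, exact and
noisy fit oracles, polar aggregation, the mirror symmetry of the 15-feature
vector under rating negation, and the QA exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rpt_uptake.rpt_features import (
    DegenerateTradeoff,
    IncompleteLimb,
    JUDGMENT_VARIABLES,
    MIRROR_SWAP,
    apply_qa,
    apply_qa_filters,
    compute_category_stats,
    compute_profiles,
    extract_judgment_profile,
    fit_limit_function,
    fit_tradeoff_function,
    fit_value_function,
)
from rpt_uptake.synthetic_cohort import CohortConfig, generate_cohort


def brute_entropy(values, levels):
    vals = [v for v in values if v in levels]
    if not vals:
        return 0.0
    h = 0.0
    for lv in levels:
        p = sum(1 for v in vals if v == lv) / len(vals)
        if p > 0:
            h -= p * np.log2(p)
    return h


class TestCategoryStats:
    def test_degenerate_all_identical(self):
        s = compute_category_stats([3] * 16)
        assert (s.K, s.sigma, s.H, s.H_plus, s.H_minus) == (3.0, 0.0, 0.0, 0.0, 0.0)

    def test_uniform_seven_levels(self):
        ratings = [lv for lv in range(-3, 4) for _ in range(2)]
        s = compute_category_stats(ratings)
        assert s.K == 0.0
        assert s.H == pytest.approx(np.log2(7))
        assert s.sigma == pytest.approx(np.sqrt(56 / 13))

    def test_mixed_example_against_brute_force(self):
        ratings = [-2, -2, 1, 1, 1, 3, 3, 3]
        s = compute_category_stats(ratings)
        assert s.K == 1.0
        assert s.H == pytest.approx(-(0.25 * np.log2(0.25) + 2 * 0.375 * np.log2(0.375)))
        assert s.H == pytest.approx(1.5613, abs=1e-4)
        assert s.H_plus == pytest.approx(1.0)
        assert s.H_minus == 0.0
        assert s.H == pytest.approx(brute_entropy(ratings, range(-3, 4)))
        assert s.H_plus == pytest.approx(brute_entropy(ratings, [1, 2, 3]))

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_category_stats([])
        with pytest.raises(ValueError):
            compute_category_stats([4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-3, 3), min_size=1, max_size=32))
    def test_entropy_bounds_and_degeneracy(self, ratings):
        s = compute_category_stats(ratings)
        assert 0.0 <= s.H <= np.log2(7) + 1e-12
        assert 0.0 <= s.H_plus <= np.log2(3) + 1e-12
        assert 0.0 <= s.H_minus <= np.log2(3) + 1e-12
        assert (s.H == 0.0) == (len(set(ratings)) == 1)
        assert -3.0 <= s.K <= 3.0
        # sharp bound for the n-1 divisor: half the sample at each scale end
        n = len(ratings)
        bound = 3.0 * np.sqrt(n / (n - 1)) if n > 1 else 0.0
        assert s.sigma <= bound + 1e-12
        if n >= 16:
            assert s.sigma <= 3.1  # the 16-rating study regime


class TestValueFunction:
    def test_exact_logarithmic_points(self):
        Ks = [0.5, 1.0, 2.0]
        pts = [(k, 2 - 0.8 * np.log(k)) for k in Ks]
        pts += [(-k, 1 + 0.3 * np.log(k)) for k in Ks]
        approach, avoidance = fit_value_function(pts)
        assert approach.a == pytest.approx(2.0)
        assert approach.b == pytest.approx(-0.8)
        assert approach.r2 == pytest.approx(1.0)
        assert avoidance.b == pytest.approx(0.3)

    def test_single_point_limb_is_incomplete(self):
        with pytest.raises(IncompleteLimb):
            fit_value_function([(1.0, 2.0), (-1.0, 2.0), (-2.0, 1.5)])

    def test_noisy_points_match_normal_equation_oracle(self, rng):
        K = np.array([0.4, 0.8, 1.2, 1.8, 2.4, 2.9])
        H = 2.0 - 0.5 * np.log(K) + rng.normal(0, 0.1, K.size)
        pts = list(zip(K, H)) + [(-k, h) for k, h in zip(K, H)]
        approach, _ = fit_value_function(pts)
        X = np.column_stack([np.ones(K.size), np.log(K)])
        beta = np.linalg.solve(X.T @ X, X.T @ H)
        assert approach.a == pytest.approx(beta[0], abs=1e-10)
        assert approach.b == pytest.approx(beta[1], abs=1e-10)
        resid = H - X @ beta
        r2_oracle = 1 - (resid @ resid) / ((H - H.mean()) @ (H - H.mean()))
        assert approach.r2 == pytest.approx(r2_oracle, abs=1e-10)


class TestLimitFunction:
    def test_exact_quadratic(self):
        K = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        s = 1 + 0.2 * K - 0.3 * K**2
        fit = fit_limit_function(list(zip(K, s)))
        assert (fit.q0, fit.q1, fit.q2) == (
            pytest.approx(1.0),
            pytest.approx(0.2),
            pytest.approx(-0.3),
        )
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_sigma(self):
        fit = fit_limit_function([(-2, 0.7), (-1, 0.7), (0, 0.7), (1, 0.7)])
        assert fit.q0 == pytest.approx(0.7)
        assert fit.q1 == pytest.approx(0.0, abs=1e-12)
        assert fit.q2 == pytest.approx(0.0, abs=1e-12)

    def test_noisy_points_match_polyfit_oracle(self, rng):
        K = np.array([-2.4, -1.4, -0.7, 0.8, 1.5, 2.4])
        s = 1.8 - 0.15 * K**2 + rng.normal(0, 0.05, K.size)
        fit = fit_limit_function(list(zip(K, s)))
        c2, c1, c0 = np.polyfit(K, s, 2)
        assert fit.q0 == pytest.approx(c0, abs=1e-10)
        assert fit.q1 == pytest.approx(c1, abs=1e-10)
        assert fit.q2 == pytest.approx(c2, abs=1e-10)

    def test_too_few_or_collinear(self):
        with pytest.raises(ValueError):
            fit_limit_function([(0, 1), (1, 1)])
        with pytest.raises(ValueError, match="collinear"):
            fit_limit_function([(1, 0.5), (1, 0.6), (1, 0.7)])


class TestTradeoffFunction:
    def test_single_diagonal_point(self):
        fit = fit_tradeoff_function([(1.0, 1.0)])
        assert fit.mean_theta == pytest.approx(45.0)
        assert fit.mean_radius == pytest.approx(np.sqrt(2))
        assert fit.theta_range == 0.0
        assert fit.radius_range == 0.0

    def test_axis_points(self):
        fit = fit_tradeoff_function([(1.0, 0.0), (0.0, 1.0)])
        assert fit.mean_theta == pytest.approx(45.0)
        assert fit.theta_range == pytest.approx(90.0)
        assert fit.mean_radius == pytest.approx(1.0)
        assert fit.radius_range == pytest.approx(0.0)

    def test_random_points_match_brute_force(self, rng):
        pts = rng.uniform(0.01, np.log2(3), size=(6, 2))
        fit = fit_tradeoff_function(pts)
        thetas = [np.degrees(np.arctan2(hm, hp)) for hp, hm in pts]
        radii = [np.hypot(hp, hm) for hp, hm in pts]
        assert fit.mean_theta == pytest.approx(np.mean(thetas))
        assert fit.theta_range == pytest.approx(max(thetas) - min(thetas))
        assert fit.mean_radius == pytest.approx(np.mean(radii))
        assert fit.radius_range == pytest.approx(max(radii) - min(radii))

    def test_origin_only_is_degenerate(self):
        with pytest.raises(DegenerateTradeoff):
            fit_tradeoff_function([(0.0, 0.0), (0.0, 0.0)])

    def test_zero_radius_points_excluded_from_angle(self):
        fit = fit_tradeoff_function([(0.0, 0.0), (1.0, 1.0)])
        assert fit.mean_theta == pytest.approx(45.0)
        assert fit.mean_radius == pytest.approx(np.sqrt(2) / 2)  # origin counted


class TestJudgmentProfile:
    def _fits(self, limit_pts):
        value = fit_value_function(
            [(0.5, 2.3), (1.0, 2.0), (2.0, 1.7), (-0.5, 2.2), (-1.0, 1.9), (-2.0, 1.5)]
        )
        tradeoff = fit_tradeoff_function([(1.0, 1.0)])
        return value, fit_limit_function(limit_pts), tradeoff

    def test_symmetric_dome_closed_form(self):
        """sigma = 2.25 - 0.25 K^2: tipping points at the scale edge, peak
        2.25, total risk = integral 0..3 = 4.5 on both sides."""
        K = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        value, limit, tradeoff = self._fits(list(zip(K, 2.25 - 0.25 * K**2)))
        prof = extract_judgment_profile(value, limit, tradeoff)
        assert prof.reward_tipping_point == pytest.approx(3.0)
        assert prof.aversion_tipping_point == pytest.approx(3.0)
        assert prof.peak_positive_risk == pytest.approx(2.25)
        assert prof.peak_negative_risk == pytest.approx(2.25)
        assert prof.total_reward_risk == pytest.approx(4.5)
        assert prof.total_aversion_risk == pytest.approx(4.5)

    def test_interior_root_bounds_the_integral(self):
        # sigma = 1 - 0.25 K^2 has roots at +-2
        K = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        value, limit, tradeoff = self._fits(list(zip(K, 1 - 0.25 * K**2)))
        prof = extract_judgment_profile(value, limit, tradeoff)
        assert prof.reward_tipping_point == pytest.approx(2.0)
        assert prof.total_reward_risk == pytest.approx(2.0 - 0.25 * 8 / 3)

    def test_symmetric_limbs_give_unit_loss_aversion(self):
        pts = [(k, 2 - 0.5 * np.log(abs(k))) for k in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0)]
        value = fit_value_function(pts)
        limit = fit_limit_function([(k, 1.0 - 0.1 * k * k) for k in (-2, -1, 0, 1, 2)])
        prof = extract_judgment_profile(value, limit, fit_tradeoff_function([(1, 1)]))
        assert prof.loss_aversion == pytest.approx(1.0)
        assert prof.risk_aversion == pytest.approx(prof.loss_resilience)


def test_mirror_symmetry_of_feature_vector():
    """Negating every rating swaps the approach/avoidance roles: the feature
    vector must map onto itself under the documented swap, loss aversion
    must invert, and the trade-off angle must reflect about 45 degrees."""
    cfg = CohortConfig(n_participants=100, seed=21)
    _, ratings, _ = generate_cohort(cfg)
    mirrored = ratings.assign(rating=-ratings["rating"])
    p1 = compute_profiles(ratings)
    p2 = compute_profiles(mirrored)
    ok = ~(p1["incomplete"] | p2["incomplete"])
    assert ok.sum() >= 80
    a, b = p1.loc[ok], p2.loc[ok]
    finite = np.isfinite(a["loss_aversion"]) & (a["loss_aversion"] > 0)
    assert np.allclose(
        b.loc[finite, "loss_aversion"], 1.0 / a.loc[finite, "loss_aversion"], rtol=1e-6
    )
    for feat, swapped in MIRROR_SWAP.items():
        assert np.allclose(b[feat], a[swapped], rtol=1e-6, atol=1e-9), feat
    assert np.allclose(
        b["reward_aversion_tradeoff"], 90.0 - a["reward_aversion_tradeoff"], atol=1e-9
    )


def test_higher_negative_overweighting_raises_median_loss_aversion():
    medians = []
    for kmean in (0.0, 0.5):
        cfg = CohortConfig(n_participants=150, seed=13, neg_overweight_mean=kmean)
        _, ratings, _ = generate_cohort(cfg)
        la = compute_profiles(ratings)["loss_aversion"].replace(np.inf, np.nan).dropna()
        medians.append(la.median())
    assert medians[1] > medians[0]


class TestQualityAssurance:
    def _row(self, **over):
        row = {n: 1.0 for n in JUDGMENT_VARIABLES}
        row.update(
            {
                "incomplete": False,
                "r2_value_approach": 0.95,
                "r2_value_avoidance": 0.9,
                "r2_limit": 0.92,
            }
        )
        row.update(over)
        return pd.Series(row)

    def test_flat_rater_dropped(self):
        keep, reasons = apply_qa_filters(np.full(96, 2), self._row())
        assert not keep and "FLAT" in reasons

    def test_near_flat_rater_dropped(self):
        ratings = np.tile([2, 3], 48)
        keep, reasons = apply_qa_filters(ratings, self._row())
        assert not keep and "NEAR_FLAT" in reasons

    def test_missing_ratings_incomplete(self):
        keep, reasons = apply_qa_filters(np.arange(-3, 4), self._row())
        assert not keep and "INCOMPLETE" in reasons

    def test_low_fit_dropped(self):
        ratings = np.resize(np.arange(-3, 4), 96)
        keep, reasons = apply_qa_filters(ratings, self._row(r2_limit=0.5))
        assert not keep and reasons == ["LOW_FIT"]

    def test_outlier_rule_uses_modified_z(self):
        ratings = np.resize(np.arange(-3, 4), 96)
        ctx = {"loss_aversion": (1.0, 0.1)}  # median 1, MAD 0.1
        keep, reasons = apply_qa_filters(
            ratings, self._row(loss_aversion=2.0), outlier_context=ctx
        )
        # z = 0.6745 * 1.0 / 0.1 = 6.7 > 4
        assert not keep and reasons == ["OUTLIER"]
        keep, _ = apply_qa_filters(
            ratings, self._row(loss_aversion=1.3), outlier_context=ctx
        )
        assert keep

    def test_speeder_only_when_time_supplied(self):
        ratings = np.resize(np.arange(-3, 4), 96)
        keep, reasons = apply_qa_filters(ratings, self._row(), completion_time=500.0)
        assert not keep and reasons == ["SPEEDER"]
        keep, _ = apply_qa_filters(ratings, self._row(), completion_time=1200.0)
        assert keep

    def test_well_spread_participant_kept(self):
        keep, reasons = apply_qa_filters(np.resize(np.arange(-3, 4), 96), self._row())
        assert keep and reasons == []

    def test_cohort_qa_is_scale_complete(self, small_cohort):
        """Every participant is either kept with 15 finite features or
        dropped with at least one recorded reason."""
        _, _, ratings, _ = small_cohort
        profiles = compute_profiles(ratings)
        qa = apply_qa(ratings, profiles)
        kept = qa.loc[qa["keep"]]
        assert np.isfinite(kept[list(JUDGMENT_VARIABLES)].to_numpy()).all()
        dropped = qa.loc[~qa["keep"], "reasons"]
        assert (dropped.str.len() > 0).all()
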