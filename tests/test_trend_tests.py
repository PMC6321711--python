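"""The ten trend-test methods: registry, weights, fits and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ordtrend as ot
from ordtrend.trend_tests import METHODS, fit_trend

from conftest import random_estimates


def replace_estimates(est, **kw):
    fields = dict(
        theta=est.theta, var_log_theta=est.var_log_theta, n=est.n,
        m_star=est.m_star, reference_index=est.reference_index,
        outcome_kind=est.outcome_kind,
    )
    fields.update(kw)
    return ot.EffectEstimates(**fields)


class TestRegistry:
    def test_ten_methods_in_order(self):
        assert sorted(METHODS) == list(range(1, 11))

    def test_invalid_methods_are_exactly_the_constrained_full_df_ones(self):
        assert {i for i, m in METHODS.items() if not m.valid} == {1, 8}
        for i in (1, 8):
            assert not METHODS[i].intercept
            assert METHODS[i].include_reference_in_df

    def test_weight_rules(self):
        rules = {i: m.weight_rule for i, m in METHODS.items()}
        assert rules[1] == rules[2] == rules[3] == "unweighted"
        assert rules[4] == "inv_var_theta"
        assert rules[5] == "inv_se_theta"
        assert rules[6] == "inv_var_log"
        assert rules[7] == "inv_se_log"
        assert rules[8] == rules[9] == rules[10] == "stratum_n"
        assert all(METHODS[i].weighted == (i >= 4) for i in METHODS)

    def test_reference_excluded_only_for_3_and_9(self):
        assert {i for i, m in METHODS.items() if not m.reference_included} == {3, 9}


class TestComputeWeights:
    def test_inverse_log_variance_weight_on_worked_example(self, diabetes):
        table, scheme = diabetes
        est = ot.odds_ratios_from_table(table, scheme)
        w6 = ot.compute_weights(METHODS[6], est)
        expected = 1.0 / (1 / 460 + 1 / 1563 + 1 / 105 + 1 / 1406)
        assert w6[3] == pytest.approx(expected, rel=1e-12)
        assert w6[3] == pytest.approx(76.64, abs=0.005)

    def test_delta_method_identity(self, diabetes):
        # inverse-variance weight for the ratio itself equals the
        # log-scale weight divided by theta squared
        table, scheme = diabetes
        est = ot.odds_ratios_from_table(table, scheme)
        w4 = ot.compute_weights(METHODS[4], est)
        w6 = ot.compute_weights(METHODS[6], est)
        mask = est.nonreference
        np.testing.assert_allclose(
            w4[mask], w6[mask] / est.theta[mask] ** 2, rtol=1e-12
        )

    def test_stratum_size_weights(self, diabetes):
        table, scheme = diabetes
        est = ot.odds_ratios_from_table(table, scheme)
        w10 = ot.compute_weights(METHODS[10], est)
        assert w10.tolist() == [93, 1511, 1918, 2023]
        w9 = ot.compute_weights(METHODS[9], est)
        assert np.isnan(w9[1])  # reference enters as an exact constraint
        assert w9[[0, 2, 3]].tolist() == [93, 1918, 2023]

    def test_reference_weight_for_unconstrained_methods(self, diabetes):
        table, scheme = diabetes
        est = ot.odds_ratios_from_table(table, scheme)
        assert ot.compute_weights(METHODS[2], est)[1] == 1.0
        assert ot.compute_weights(METHODS[8], est)[1] == est.n[1]

    def test_zero_variance_under_variance_rule_raises(self):
        rng = np.random.default_rng(1)
        est = random_estimates(rng)
        var = est.var_log_theta.copy()
        var[2] = 0.0
        bad = replace_estimates(est, var_log_theta=var)
        with pytest.raises(ot.DegenerateWeightError):
            ot.compute_weights(METHODS[6], bad)


class TestFitTrend:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_shared_through_origin_normal_equations(self, seed):
        # methods 1/3 and 8/9 share slope and SSE; only df differs
        est = random_estimates(np.random.default_rng(seed))
        for a, b in ((1, 3), (8, 9)):
            ra = fit_trend(METHODS[a], est)
            rb = fit_trend(METHODS[b], est)
            assert ra.slope == pytest.approx(rb.slope, rel=1e-12)
            # equal SSE at different df: SE ratio is sqrt(df_b/df_a)
            assert ra.slope_se * np.sqrt(ra.df) == pytest.approx(
                rb.slope_se * np.sqrt(rb.df), rel=1e-12
            )
            assert ra.df == rb.df + 1
            assert ra.p_value < rb.p_value

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(-0.5, 0.5))
    def test_location_invariance_of_intercept_methods(self, seed, shift):
        est = random_estimates(np.random.default_rng(seed))
        for mid in (2, 10):
            base = fit_trend(METHODS[mid], est)
            # shifting every centered effect size by a constant moves
            # only the intercept; slope and p must not change.  The
            # reference convention theta_ref = 1 must be relaxed to
            # express the shift, so the fit is re-run on raw values.
            x = est.m_star
            y = (est.theta - 1.0) + shift
            w = ot.compute_weights(METHODS[mid], est)
            sw, xb, yb = w.sum(), (w * x).sum() / w.sum(), (w * y).sum() / w.sum()
            slope = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
            assert slope == pytest.approx(base.slope, rel=1e-10, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0))
    def test_scale_equivariance(self, seed, c):
        # scaling theta* by c scales slopes by c and leaves p alone for
        # every method whose weights do not involve theta itself
        est = random_estimates(np.random.default_rng(seed))
        scaled = replace_estimates(est, theta=1.0 + c * (est.theta - 1.0))
        for mid in (1, 2, 3, 6, 7, 8, 9, 10):
            a = fit_trend(METHODS[mid], est)
            b = fit_trend(METHODS[mid], scaled)
            assert b.slope == pytest.approx(c * a.slope, rel=1e-9)
            assert b.p_value == pytest.approx(a.p_value, rel=1e-9)

    def test_perfect_linear_fit_reports_zero_p(self, scheme):
        est = ot.EffectEstimates(
            theta=1.0 + 0.1 * scheme.m_star,
            var_log_theta=np.array([0.02, 0.0, 0.02, 0.02]),
            n=np.array([100, 100, 100, 100]),
            m_star=scheme.m_star,
            reference_index=1,
            outcome_kind="binary",
        )
        res = fit_trend(METHODS[2], est)
        assert res.slope == pytest.approx(0.1, rel=1e-12)
        assert res.p_value == 0.0
        assert "exact-fit" in res.flags

    def test_no_variation_reports_p_one(self, scheme):
        est = ot.EffectEstimates(
            theta=np.ones(4),
            var_log_theta=np.array([0.1, 0.0, 0.1, 0.1]),
            n=np.array([50, 50, 50, 50]),
            m_star=scheme.m_star,
            reference_index=1,
            outcome_kind="binary",
        )
        for res in ot.run_all_methods(est):
            assert res.p_value == 1.0
            assert "no-variation" in res.flags

    def test_stronger_trend_gives_smaller_p(self, scheme):
        noise = np.array([0.013, 0.0, -0.009, 0.011])
        previous = {i: 1.1 for i in ot.VALID_METHOD_IDS}
        for c in (0.02, 0.05, 0.1, 0.15):  # keep every ratio positive
            est = ot.EffectEstimates(
                theta=1.0 + c * scheme.m_star + noise,
                var_log_theta=np.array([0.02, 0.0, 0.02, 0.02]),
                n=np.array([100, 1500, 1900, 2000]),
                m_star=scheme.m_star,
                reference_index=1,
                outcome_kind="binary",
            )
            for res in ot.run_all_methods(est, ot.VALID_METHOD_IDS):
                assert res.p_value < previous[res.method_id]
                previous[res.method_id] = res.p_value

    def test_too_few_classes_rejected(self):
        est = ot.EffectEstimates(
            theta=np.array([1.0, 1.3]),
            var_log_theta=np.array([0.0, 0.1]),
            n=np.array([10, 10]),
            m_star=np.array([0.0, 5.0]),
            reference_index=0,
            outcome_kind="binary",
        )
        with pytest.raises(ValueError):
            fit_trend(METHODS[2], est)


class TestRunAllMethods:
    def test_batch_order_and_count(self, diabetes):
        table, scheme = diabetes
        res = ot.run_all_methods(ot.odds_ratios_from_table(table, scheme))
        assert [r.method_id for r in res] == list(range(1, 11))

    def test_per_method_failures_recorded_not_fatal(self):
        rng = np.random.default_rng(2)
        est = random_estimates(rng)
        var = est.var_log_theta.copy()
        var[0] = 0.0  # breaks the variance-based weight rules only
        est = replace_estimates(est, var_log_theta=var)
        res = ot.run_all_methods(est)
        failed = {r.method_id for r in res if r.flags and r.flags[0].startswith("error")}
        assert failed == {4, 5, 6, 7}
        for r in res:
            if r.method_id not in failed:
                assert np.isfinite(r.p_value)

    def test_results_frame_round_trips_pvalues(self, diabetes):
        table, scheme = diabetes
        res = ot.run_all_methods(ot.odds_ratios_from_table(table, scheme))
        frame = ot.results_to_frame(res)
        assert frame.shape[0] == 10
        np.testing.assert_allclose(
            frame["p"].to_numpy(), [r.p_value for r in res]
        )
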