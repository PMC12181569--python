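"""Kaplan–Meier, log-rank, Cox fits, BH, and the cutoff scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter

import oracles
from senscan import (
    bh_adjust,
    binary_cox_fit,
    cox_fit,
    cox_score_statistic,
    cutoff_scan,
    km_estimate,
    logrank_test,
)
from senscan.survival import ConvergenceError, DegenerateSplitError
from senscan.types import PipelineError

from conftest import random_survival


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([2, 4, 6], [1, 1, 0])
        np.testing.assert_allclose(km.event_times, [2, 4])
        np.testing.assert_allclose(km.surv, [2 / 3, 1 / 3])
        np.testing.assert_array_equal(km.n_at_risk, [3, 2])
        assert km.median_months == 4

    def test_no_events_flat_curve_undefined_median(self):
        km = km_estimate([5, 10, 15], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.median_months is None

    def test_everyone_events_at_one(self):
        km = km_estimate([1, 1, 1, 1], [1, 1, 1, 1])
        np.testing.assert_allclose(km.surv, [0.0])
        assert km.median_months == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 30))
            t, d = random_survival(rng, n)
            if d.sum() == 0:
                continue
            km = km_estimate(t, d)
            et, surv, risk, median = oracles.km_brute_force(t, d)
            np.testing.assert_allclose(km.event_times, et)
            np.testing.assert_allclose(km.surv, surv, rtol=1e-12)
            np.testing.assert_array_equal(km.n_at_risk, risk)
            assert km.median_months == median


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([3.0, 5.0, 8.0, 3.0, 5.0, 8.0])
        d = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi, p = logrank_test(t, d, g)
        assert chi == pytest.approx(0.0, abs=1e-12)

    def test_six_subject_fixture_matches_observed_minus_expected(self):
        t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        d = np.array([1, 1, 0, 1, 1, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi, p = logrank_test(t, d, g)
        chi_oracle, p_oracle = oracles.logrank_brute_force(t, d, g)
        assert chi == pytest.approx(chi_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2, 3], [1, 1, 0], [1, 1, 1])

    def test_null_permutation_p_values_are_uniform(self, rng):
        t, d = random_survival(rng, 60)
        ps = []
        for _ in range(300):
            g = rng.permutation(np.repeat([0, 1], 30)).astype(bool)
            ps.append(logrank_test(t, d, g)[1])
        from scipy import stats

        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3  # no gross departure from uniformity


class TestBinaryCox:
    def test_matches_lifelines_with_and_without_ties(self, rng):
        worst = 0.0
        for _ in range(40):
            n = int(rng.integers(25, 90))
            x = rng.integers(0, 2, n)
            decimals = int(rng.integers(0, 3))  # 0 -> heavy ties
            t = np.round(rng.exponential(20, n) * np.exp(-0.6 * x), decimals) + 0.5
            d = (rng.random(n) < 0.6).astype(int)
            if (d * x).sum() == 0 or (d * (1 - x)).sum() == 0:
                continue
            mine = binary_cox_fit(x, t, d)
            cph = CoxPHFitter()
            cph.fit(
                pd.DataFrame({"x": x, "t": t, "d": d}),
                "t",
                "d",
                fit_options={"precision": 1e-10},
            )
            worst = max(
                worst,
                abs(mine.beta[0] - cph.params_["x"]),
                abs(mine.se[0] - cph.standard_errors_["x"]),
            )
        # agreement is limited by lifelines' own stopping rule
        assert worst < 1e-4

    def test_score_statistic_equals_logrank_without_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            x = rng.integers(0, 2, n)
            t = rng.exponential(20, n)  # continuous: tie-free a.s.
            d = (rng.random(n) < 0.7).astype(int)
            if x.sum() in (0, n) or (d * x).sum() + (d * (1 - x)).sum() == 0:
                continue
            chi, _ = logrank_test(t, d, x.astype(bool))
            assert cox_score_statistic(x, t, d) == pytest.approx(chi, abs=1e-8)

    def test_efron_and_breslow_coincide_without_ties(self, rng):
        x = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        t = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0])
        d = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        efron = binary_cox_fit(x, t, d, ties="efron")
        breslow = binary_cox_fit(x, t, d, ties="breslow")
        assert efron.beta[0] == pytest.approx(breslow.beta[0], abs=1e-9)

    def test_separation_is_diagnosed(self):
        # all events in the high group -> monotone likelihood
        x = np.array([1, 1, 1, 0, 0, 0])
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        d = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(DegenerateSplitError):
            binary_cox_fit(x, t, d)

    def test_null_covariate_recovers_hr_one(self, rng):
        betas = []
        for _ in range(30):
            n = 300
            x = rng.integers(0, 2, n)
            t = rng.exponential(20, n)
            d = (rng.random(n) < 0.7).astype(int)
            betas.append(binary_cox_fit(x, t, d).beta[0])
        assert np.mean(betas) == pytest.approx(0.0, abs=0.05)


class TestCoxFitGeneral:
    def test_recovers_known_coefficient(self, rng):
        betas = []
        for _ in range(5):
            n = 600
            z = rng.normal(0, 1, n)
            t = rng.exponential(1.0 / (0.05 * np.exp(-0.4 * z)))
            c = rng.exponential(30, n)
            obs = np.minimum(t, c)
            d = (t <= c).astype(int)
            res = cox_fit(pd.DataFrame({"z": z}), obs, d)
            betas.append(res.beta[0])
        assert np.mean(betas) == pytest.approx(-0.4, abs=0.06)

    def test_constant_covariate_rejected(self, rng):
        t, d = random_survival(rng, 30)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"z": np.ones(30)}), t, d)

    def test_result_invariants(self, rng):
        n = 100
        z = rng.normal(0, 1, n)
        t, d = random_survival(rng, n)
        res = cox_fit(pd.DataFrame({"z": z}), t, d)
        assert res.hr[0] == pytest.approx(np.exp(res.beta[0]))
        assert res.ci95[0, 0] < res.hr[0] < res.ci95[0, 1]
        assert res.n_events == d.sum() and res.n_used == n


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_step_up_triple(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25
        )
    )
    def test_q_dominates_p_and_matches_definition(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(q, oracles.bh_brute_force(p), atol=1e-12)


class TestCutoffScan:
    def test_constant_scores_is_scan_error(self, rng):
        t, d = random_survival(rng, 20)
        with pytest.raises(PipelineError):
            cutoff_scan(np.full(20, 5.0), t, d)

    def test_matches_exhaustive_enumeration(self, rng):
        scores = rng.lognormal(6.5, 0.4, 20)
        t, d = random_survival(rng, 20, event_rate=0.7)
        scan = cutoff_scan(scores, t, d)
        cut_o, p_o, hr_o = oracles.scan_brute_force(scores, t, d)
        np.testing.assert_allclose(scan.cutoffs, cut_o)
        np.testing.assert_allclose(scan.p_at, p_o, rtol=1e-5, atol=1e-9)
        np.testing.assert_allclose(scan.hr_at, hr_o, rtol=1e-5)
        sel_o = oracles.select_brute_force(cut_o, p_o, hr_o)
        assert p_o[scan.selected_index] <= p_o[sel_o] * (1 + 1e-6)

    def test_monotone_transform_preserves_partition_and_p(self, rng):
        scores = rng.lognormal(6.5, 0.5, 40)
        t, d = random_survival(rng, 40, event_rate=0.7)
        a = cutoff_scan(scores, t, d)
        b = cutoff_scan(np.log(scores) ** 3 + 7.0, t, d)
        np.testing.assert_allclose(a.p_at, b.p_at, rtol=1e-10)
        assert a.selected_index == b.selected_index
        assert a.selected_p == pytest.approx(b.selected_p, rel=1e-10)
        np.testing.assert_array_equal(a.n_high_at, b.n_high_at)

    def test_selected_attains_minimum_with_strongest_hr_tie_break(self):
        from senscan.survival import select_cutoff_index

        cutoffs = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([0.2, 0.01, 0.01, 0.5])
        beta = np.array([0.1, -0.3, 0.8, 0.2])
        assert select_cutoff_index(cutoffs, p, beta) == 2
        beta_tied = np.array([0.1, 0.8, -0.8, 0.2])
        assert select_cutoff_index(cutoffs, p, beta_tied) == 1

    def test_quartile_bounds_respected_and_km_groups_attached(self, rng):
        scores = rng.lognormal(6.5, 0.5, 80)
        t, d = random_survival(rng, 80, event_rate=0.7)
        scan = cutoff_scan(scores, t, d)
        q1, q3 = np.quantile(scores, [0.25, 0.75])
        assert scan.cutoffs.min() >= q1 and scan.cutoffs.max() <= q3
        n_high = int((scores > scan.selected_cutoff).sum())
        assert len(scan.km_high.event_times) <= n_high
        assert scan.n_high_at[scan.selected_index] == n_high
        assert (scan.q_at >= scan.p_at - 1e-15).all()
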