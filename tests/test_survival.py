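"""KM / log-rank / Cox / concordance, checked against hand oracles and
lifelines as the independent reference implementation."""

import numpy as np
import pytest

from tp53state.survival import (SurvivalSample, cox_fit, harrell_c,
                                km_estimate, km_median, logrank_test)


def brute_force_c(times, events, risks):
    """Exhaustive pair enumeration under the documented convention."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den if den else float("nan")


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        curve = km_estimate(SurvivalSample([5, 8, 12], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.median is None

    def test_hand_product_limit(self):
        curve = km_estimate(SurvivalSample([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2

    def test_single_subject_event(self):
        curve = km_estimate(SurvivalSample([5], [1]))
        assert curve.survival[-1] == 0.0
        assert curve.median == 5

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            km_estimate(SurvivalSample([], []))

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=200)
        curve = km_estimate(SurvivalSample(t, np.ones(200, bool)))
        for et, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > et).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = np.round(rng.exponential(20, 300), 0)  # force ties
        e = rng.random(300) < 0.7
        curve = km_estimate(SurvivalSample(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-6)
        assert km_median(t, e) == pytest.approx(kmf.median_survival_time_)

    def test_survival_monotone_and_bounded(self, rng):
        t = rng.exponential(10, 150)
        e = rng.random(150) < 0.5
        curve = km_estimate(SurvivalSample(t, e))
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))


class TestLogrank:
    def test_identical_groups_null(self):
        g = SurvivalSample([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([SurvivalSample([1], [1]), SurvivalSample([], [])])

    def test_matches_lifelines_two_group(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t1 = np.round(rng.exponential(10, 120), 0)
        t2 = np.round(rng.exponential(20, 150), 0)
        e1 = rng.random(120) < 0.8
        e2 = rng.random(150) < 0.8
        chi2, p = logrank_test([SurvivalSample(t1, e1),
                                SurvivalSample(t2, e2)])
        ref = ll_logrank(t1, t2, e1, e2)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
        assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_matches_lifelines_three_group(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = np.round(np.concatenate([
            rng.exponential(m, 80) for m in (8, 14, 25)]), 0)
        events = rng.random(240) < 0.75
        labels = np.repeat([0, 1, 2], 80)
        groups = [SurvivalSample(times[labels == g], events[labels == g])
                  for g in range(3)]
        chi2, p = logrank_test(groups)
        ref = multivariate_logrank_test(times, labels, events)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)

    def test_detects_strong_hazard_difference(self, rng):
        hits = 0
        for rep in range(20):
            t1 = rng.exponential(10, 500)
            t2 = rng.exponential(30, 500)
            c = rng.uniform(0, 120, 1000)
            times = np.concatenate([np.minimum(t1, c[:500]),
                                    np.minimum(t2, c[500:])])
            events = np.concatenate([t1 <= c[:500], t2 <= c[500:]])
            _, p = logrank_test([
                SurvivalSample(times[:500], events[:500]),
                SurvivalSample(times[500:], events[500:])])
            hits += p < 0.001
        assert hits >= 19  # HR 3 at n=500/group is essentially always seen


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        t = rng.exponential(20, 800)
        e = rng.random(800) < 0.8
        x = rng.normal(size=800)
        out = cox_fit(SurvivalSample(t, e), x)
        assert out["hr"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_sign_flip_symmetry(self, rng):
        t = rng.exponential(20, 300)
        e = rng.random(300) < 0.8
        x = (rng.random(300) < 0.5).astype(float)
        a = cox_fit(SurvivalSample(t, e), x)
        b = cox_fit(SurvivalSample(t, e), 1 - x)
        assert a["log_hr"].iloc[0] == pytest.approx(-b["log_hr"].iloc[0],
                                                    abs=1e-6)

    def test_recovers_planted_hazard_ratio(self, rng):
        ok = 0
        for rep in range(10):
            x = (rng.random(2000) < 0.5).astype(float)
            lam = 0.02 * np.exp(np.log(2.0) * x)
            te = rng.exponential(1 / lam)
            tc = rng.uniform(0, 200, 2000)
            out = cox_fit(SurvivalSample(np.minimum(te, tc), te <= tc), x)
            ok += 1.8 <= out["hr"].iloc[0] <= 2.2
        assert ok >= 9

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            cox_fit(SurvivalSample([1, 2], [0, 0]), [0.0, 1.0])


class TestConcordance:
    def test_perfect_anti_ranking(self):
        t = np.array([1.0, 2, 3, 4, 5])
        risks = np.array([5.0, 4, 3, 2, 1])
        c = harrell_c(SurvivalSample(t, np.ones(5, bool)), risks)
        assert c == 1.0

    def test_constant_risks_half(self):
        t = np.array([1.0, 2, 3, 4])
        c = harrell_c(SurvivalSample(t, np.ones(4, bool)), np.zeros(4))
        assert c == 0.5

    def test_five_subject_worked_example(self):
        times = np.array([2.0, 4, 4, 6, 9])
        events = np.array([1, 1, 0, 1, 0], bool)
        risks = np.array([0.9, 0.4, 0.7, 0.6, 0.1])
        c = harrell_c(SurvivalSample(times, events), risks)
        assert c == pytest.approx(brute_force_c(times, events, risks))

    def test_equals_brute_force_random(self, rng):
        for _ in range(10):
            t = np.round(rng.exponential(10, 50), 0)
            e = rng.random(50) < 0.6
            risks = rng.normal(size=50)
            sample = SurvivalSample(t, e)
            expected = brute_force_c(t, e, risks)
            got = harrell_c(sample, risks)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.7
        risks = rng.normal(size=80)
        s = SurvivalSample(t, e)
        assert harrell_c(s, risks) == pytest.approx(
            harrell_c(s, np.exp(3 * risks)))

    def test_negation_complements(self, rng):
        t = rng.exponential(10, 60)   # continuous: no risk ties
        e = rng.random(60) < 0.7
        risks = rng.normal(size=60)
        s = SurvivalSample(t, e)
        assert harrell_c(s, risks) + harrell_c(s, -risks) == pytest.approx(1.0)

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines.utils import concordance_index

        t = rng.exponential(10, 200)  # continuous times: conventions agree
        e = rng.random(200) < 0.7
        risks = rng.normal(size=200)
        c = harrell_c(SurvivalSample(t, e), risks)
        # lifelines scores low predicted value = high risk
        ref = concordance_index(t, -risks, e)
        assert c == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_nan(self):
        c = harrell_c(SurvivalSample([3.0, 3.0], [True, True]), [1.0, 2.0])
        assert np.isnan(c)
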