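import math

import numpy as np
import pytest

from ppsn.survival import (
    YEARS_3,
    YEARS_5,
    SurvivalData,
    horizon_binary_outcome,
    km_estimate,
    log_rank,
    restrict_horizon,
)


def sd(times, events, groups=None):
    return SurvivalData(
        time=np.asarray(times, float),
        event=np.asarray(events, bool),
        group=None if groups is None else np.asarray(groups),
    )


class TestKaplanMeier:
    def test_two_deaths_no_censoring(self):
        km = km_estimate(sd([1, 2], [1, 1]))
        assert km.survival_at(1) == 0.5
        assert km.survival_at(2) == 0.0
        assert list(km.at_risk) == [2, 1]

    def test_censoring_shrinks_risk_set(self):
        # event at 1 (S=2/3), censor at 2, event at 3 on a risk set of 1
        km = km_estimate(sd([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.n_censored == 1

    def test_hand_product_limit(self):
        # n=4: event at 1 -> 3/4; censor at 2; event at 3 on risk 2 -> 3/8
        km = km_estimate(sd([1, 2, 3, 4], [1, 0, 1, 0]))
        assert km.survival_at(1) == pytest.approx(3 / 4)
        assert km.survival_at(3) == pytest.approx(3 / 8)
        assert km.survival_at(0.5) == 1.0

    def test_all_censored_flat_at_one(self):
        km = km_estimate(sd([5, 6, 7], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0
        assert km.n_censored == 3

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 50, size=40).astype(float)
        km = km_estimate(sd(times, [1] * 40))
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_event_before_censor_tie_rule(self):
        # censored subject at t stays in the risk set for the event at t
        km = km_estimate(sd([5, 5], [1, 0]))
        assert km.survival_at(5) == 0.5
        assert list(km.at_risk) == [2]

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.integers(1, 30, size=60).astype(float)
        events = rng.uniform(size=60) < 0.6
        km = km_estimate(sd(times, events))
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestLogRank:
    def test_identical_experience_chi2_zero(self):
        data = sd([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0], list("AAABBB"))
        res = log_rank(data, ("A", "B"))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        """O, E, V worked by hand: A = {1e, 3e, 5c}, B = {2e, 4c, 6e}
        gives O_A=2, E_A=1.4, V=0.74, chi2=0.36/0.74."""
        data = sd([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 1], list("AAABBB"))
        res = log_rank(data, ("A", "B"))
        assert res.observed == (2.0, 2.0)
        assert res.expected[0] == pytest.approx(1.4, abs=1e-12)
        assert res.chi2 == pytest.approx(0.36 / 0.74, abs=1e-12)
        # expected totals preserve observed totals
        assert sum(res.expected) == pytest.approx(sum(res.observed))

    def test_label_swap_invariance(self, rng):
        times = rng.integers(1, 40, size=50).astype(float)
        events = rng.uniform(size=50) < 0.7
        groups = np.where(rng.uniform(size=50) < 0.5, "A", "B")
        a = log_rank(sd(times, events, groups), ("A", "B"))
        b = log_rank(sd(times, events, groups), ("B", "A"))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_one_df_identity(self, rng):
        """chi2 equals the squared standardized O-E of either group."""
        times = rng.integers(1, 40, size=50).astype(float)
        events = rng.uniform(size=50) < 0.7
        groups = np.where(rng.uniform(size=50) < 0.5, "A", "B")
        res = log_rank(sd(times, events, groups), ("A", "B"))
        d1 = res.observed[0] - res.expected[0]
        d2 = res.observed[1] - res.expected[1]
        assert d1 == pytest.approx(-d2, abs=1e-9)

    def test_matches_lifelines(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        times = rng.integers(1, 30, size=80).astype(float)
        events = rng.uniform(size=80) < 0.6
        groups = np.where(rng.uniform(size=80) < 0.5, "A", "B")
        mine = log_rank(sd(times, events, groups), ("A", "B"))
        ll = lifelines_stats.logrank_test(
            times[groups == "A"], times[groups == "B"],
            events[groups == "A"], events[groups == "B"],
        )
        assert mine.chi2 == pytest.approx(float(ll.test_statistic), rel=1e-9)
        assert mine.p == pytest.approx(float(ll.p_value), rel=1e-6)

    def test_empty_group_raises(self):
        data = sd([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(ValueError):
            log_rank(data, ("A", "B"))


class TestHorizonRestriction:
    def test_event_beyond_horizon_becomes_censoring(self):
        out = restrict_horizon(sd([1200], [1]), YEARS_3)
        assert out.time[0] == YEARS_3 and not out.event[0]

    def test_event_within_horizon_unchanged(self):
        out = restrict_horizon(sd([900], [1]), YEARS_3)
        assert out.time[0] == 900 and out.event[0]

    def test_infinite_horizon_identity(self):
        data = sd([100, 2000], [1, 0])
        out = restrict_horizon(data, math.inf)
        assert np.array_equal(out.time, data.time)
        assert np.array_equal(out.event, data.event)

    def test_idempotent_and_commutes(self, rng):
        data = sd(rng.integers(1, 3000, size=30).astype(float),
                  rng.uniform(size=30) < 0.5)
        once = restrict_horizon(data, YEARS_3)
        twice = restrict_horizon(once, YEARS_3)
        assert np.array_equal(once.time, twice.time)
        assert np.array_equal(once.event, twice.event)
        ab = restrict_horizon(restrict_horizon(data, YEARS_5), YEARS_3)
        ba = restrict_horizon(restrict_horizon(data, YEARS_3), YEARS_5)
        direct = restrict_horizon(data, min(YEARS_3, YEARS_5))
        for other in (ab, ba):
            assert np.array_equal(other.time, direct.time)
            assert np.array_equal(other.event, direct.event)


class TestHorizonBinary:
    def test_classification_rules(self):
        data = sd([400, 2000, 500], [1, 0, 0])
        out = horizon_binary_outcome(data, YEARS_3)
        assert list(out.included) == [True, True, False]
        assert list(out.event) == [True, False]
        assert out.n_excluded == 1

    def test_death_after_horizon_counts_negative(self):
        out = horizon_binary_outcome(sd([2000], [1]), YEARS_3)
        assert list(out.event) == [False]

    def test_infinite_horizon_keeps_everyone(self):
        data = sd([100, 500], [1, 0])
        out = horizon_binary_outcome(data, math.inf)
        assert out.n_excluded == 0
        assert list(out.event) == [True, False]

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            horizon_binary_outcome(sd([10, 20], [0, 0]), YEARS_3)
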