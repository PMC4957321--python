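"""Model layer: conjugate update, closed-form predictives, MC cross-checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import accrualpred as ap
from accrualpred.model import ApproximationValidityWarning, WindowExceededError


def make_obs(m: int, Tm: float) -> ap.AccrualObservation:
    """Observation with m enrollments evenly spread over (0, Tm]."""
    if m == 0:
        return ap.AccrualObservation.empty(Tm=Tm)
    times = np.linspace(Tm / m, Tm, m) if Tm > 0 else np.zeros(m)
    return ap.AccrualObservation(times, Tm=Tm)


class TestTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=0, T=24, P=0.5), dict(n=158, T=0, P=0.5),
         dict(n=158, T=24, P=0.0), dict(n=158, T=24, P=1.5)],
    )
    def test_design_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ap.StudyDesign(**kwargs)

    def test_observation_rejects_unsorted_and_negative(self):
        with pytest.raises(ValueError):
            ap.AccrualObservation([3.0, 1.0])
        with pytest.raises(ValueError):
            ap.AccrualObservation([-1.0, 2.0])
        with pytest.raises(ValueError):
            ap.AccrualObservation([5.0], Tm=4.0)

    def test_observation_allows_ties_and_censored_gap(self):
        obs = ap.AccrualObservation([2.0, 2.0, 5.0], Tm=9.0)
        assert obs.m == 3
        assert obs.Tm == 9.0
        np.testing.assert_allclose(obs.waiting_times, [2.0, 0.0, 3.0])

    def test_strict_clock_stops_at_last_enrollment(self):
        obs = ap.AccrualObservation.at_last_enrollment([1.0, 4.0])
        assert obs.Tm == 4.0


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "m,Tm,expected",
        [(0, 0.0, (79.0, 12.0)),   # no data: the prior IG(nP, TP)
         (50, 10.0, (129.0, 22.0))],
    )
    def test_conjugate_update(self, planning_design, m, Tm, expected):
        state = ap.update_posterior(planning_design, make_obs(m, Tm))
        assert (state.r, state.s) == expected

    def test_posterior_density_integrates_to_one(self, planning_design):
        """Quadrature of the hand-written inverse-gamma density over (0, inf)."""
        state = ap.update_posterior(planning_design, make_obs(50, 10.0))
        r, s = state.r, state.s

        def density(theta):
            # log-space evaluation of s^r / Gamma(r) * theta^-(r+1) * exp(-s/theta)
            return math.exp(r * math.log(s) - math.lgamma(r)
                            - (r + 1) * math.log(theta) - s / theta)

        total, err = integrate.quad(density, 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)
        # and scipy's parametrization agrees with the hand-written density
        grid = np.linspace(0.05, 0.5, 7)
        np.testing.assert_allclose(
            [density(t) for t in grid], state.distribution.pdf(grid), rtol=1e-10
        )

    @given(
        m1=st.integers(0, 200), m2=st.integers(0, 200),
        t1=st.floats(0, 50), t2=st.floats(0, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_incremental_updates_pool(self, m1, m2, t1, t2):
        """Two sequential updates equal one pooled update (additivity in (m, Tm))."""
        design = ap.StudyDesign(n=100, T=30, P=0.3)
        once = ap.update_posterior(design, make_obs(m1 + m2, t1 + t2))
        mid = ap.update_posterior(design, make_obs(m1, t1))
        # treat the intermediate posterior as the prior of a fresh design-equivalent
        twice_r = mid.r + m2
        twice_s = mid.s + t2
        assert (once.r, once.s) == pytest.approx((twice_r, twice_s))


class TestCountPrediction:
    def test_prior_state_params(self, planning_design, no_data):
        cp = ap.predictive_count_params(planning_design, no_data)
        assert cp.r == 79.0
        assert cp.p == pytest.approx(1 / 3)

    def test_window_exhausted_gives_p_one(self, planning_design):
        cp = ap.predictive_count_params(planning_design, make_obs(100, 24.0))
        assert cp.p == 1.0

    def test_window_exceeded_raises(self, planning_design):
        with pytest.raises(WindowExceededError):
            ap.predictive_count_params(planning_design, make_obs(100, 25.0))

    @given(P=st.floats(0.001, 1.0), T=st.floats(1.0, 100.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_p_bounded_at_halfway(self, P, T):
        """At Tm = T/2 the predictive probability lies in (0.5, 0.75]."""
        design = ap.StudyDesign(n=100, T=T, P=P)
        cp = ap.predictive_count_params(design, make_obs(0, T / 2))
        assert 0.5 < cp.p <= 0.75

    @given(n=st.integers(1, 2000), T=st.floats(0.5, 200), P=st.floats(0.001, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_prior_predictive_mean_is_target(self, n, T, P):
        """With no data the predictive count mean is exactly the target n."""
        cp = ap.predictive_count_params(ap.StudyDesign(n, T, P), ap.AccrualObservation.empty())
        assert cp.mean_total == pytest.approx(n, rel=1e-12)

    def test_exact_interval_matches_planning_example(self, planning_design, no_data):
        cp = ap.predictive_count_params(planning_design, no_data)
        lo, hi = ap.count_interval_exact(cp, 0.95)
        assert lo == 118
        assert hi == 203

    def test_exhausted_window_collapses_to_observed(self):
        cp = ap.CountPrediction(r=79, p=1.0, horizon_T=24, m=37, Tm=24)
        assert ap.count_interval_exact(cp, 0.95) == (37, 37)

    def test_exact_interval_matches_two_stage_sampling(self, planning_design, no_data):
        """Equal-tailed NB quantiles vs theta-then-Poisson simulation."""
        cp = ap.predictive_count_params(planning_design, no_data)
        lo, hi = ap.count_interval_exact(cp, 0.95)
        rng = np.random.default_rng(20160722)
        theta = stats.invgamma.rvs(79, scale=12, size=200_000, random_state=rng)
        eta = rng.poisson(24.0 / theta)
        mc_lo, mc_hi = np.quantile(eta, [0.025, 0.975])
        assert abs(lo - mc_lo) <= 2
        assert abs(hi - mc_hi) <= 2

    def test_normal_moments(self, planning_design, no_data):
        cp = ap.predictive_count_params(planning_design, no_data)
        assert cp.mean_total == pytest.approx(158.0)
        assert math.sqrt(cp.var_remaining) == pytest.approx(math.sqrt(474), rel=1e-12)

    def test_normal_interval_close_to_exact(self, planning_design, no_data):
        cp = ap.predictive_count_params(planning_design, no_data)
        exact = ap.count_interval_exact(cp, 0.95)
        approx = ap.count_interval_normal(cp, 0.95)
        assert abs(approx[0] - exact[0]) <= 4
        assert abs(approx[1] - exact[1]) <= 4

    def test_normal_warns_outside_validity_region(self):
        with pytest.warns(ApproximationValidityWarning):
            ap.count_interval_normal(ap.CountPrediction(r=79, p=0.999, horizon_T=24))
        with pytest.warns(ApproximationValidityWarning):
            ap.count_interval_normal(ap.CountPrediction(r=5, p=0.5, horizon_T=24))

    def test_interval_monotone_in_window(self, planning_design):
        """Holding the posterior fixed, a longer window can only raise the endpoints."""
        state = ap.update_posterior(planning_design, make_obs(40, 8.0))
        TP = planning_design.T * planning_design.P
        prev = (0, 0)
        for horizon in np.linspace(8.0, 40.0, 17):
            p = (TP + 8.0) / (TP + horizon)
            cp = ap.CountPrediction(r=state.r, p=p, horizon_T=horizon, m=40, Tm=8.0)
            iv = ap.count_interval_exact(cp, 0.95)
            assert iv[0] >= prev[0] and iv[1] >= prev[1]
            prev = iv


class TestTimePrediction:
    def test_exact_interval_matches_planning_example(self, planning_design, no_data):
        tp = ap.time_prediction(planning_design, no_data)
        lo, hi = ap.time_interval_exact(tp, 0.95)
        assert lo == pytest.approx(18.5, abs=0.1)
        assert hi == pytest.approx(31.7, abs=0.1)

    def test_nothing_left_to_recruit(self):
        tp = ap.TimePrediction(k=0, r=79, s=12, Tm=14.0)
        assert ap.time_interval_exact(tp, 0.95) == (14.0, 14.0)

    def test_exact_interval_matches_two_stage_sampling(self, planning_design, no_data):
        """Beta-quantile transform vs theta-then-gamma simulation."""
        tp = ap.time_prediction(planning_design, no_data)
        lo, hi = ap.time_interval_exact(tp, 0.95)
        rng = np.random.default_rng(558)
        theta = stats.invgamma.rvs(79, scale=12, size=200_000, random_state=rng)
        t_rem = rng.gamma(shape=158, scale=theta)
        mc_lo, mc_hi = np.quantile(t_rem, [0.025, 0.975])
        assert lo == pytest.approx(mc_lo, abs=0.2)
        assert hi == pytest.approx(mc_hi, abs=0.2)

    def test_normal_mean(self, planning_design, no_data):
        tp = ap.time_prediction(planning_design, no_data)
        assert tp.mean_total == pytest.approx(12 * 158 / 78, rel=1e-12)

    def test_normal_interval_close_to_exact(self, planning_design, no_data):
        """The beta prime is right-skewed, so the symmetric approximation shifts
        both endpoints down by under one time unit at this sample size."""
        tp = ap.time_prediction(planning_design, no_data)
        exact = ap.time_interval_exact(tp, 0.95)
        approx = ap.time_interval_normal(tp, 0.95)
        assert approx[0] == pytest.approx(exact[0], abs=1.0)
        assert approx[1] == pytest.approx(exact[1], abs=1.0)

    def test_normal_requires_finite_variance(self):
        with pytest.raises(ValueError, match="r > 2"):
            ap.time_interval_normal(ap.TimePrediction(k=10, r=2.0, s=5.0))

    def test_interval_monotone_in_remaining_count(self):
        prev = (0.0, 0.0)
        for k in (1, 5, 20, 80, 158):
            iv = ap.time_interval_exact(ap.TimePrediction(k=k, r=79, s=12), 0.95)
            assert iv[0] >= prev[0] and iv[1] >= prev[1]
            prev = iv


class TestEventConsistency:
    def test_count_and_time_views_agree(self):
        """'Recruit the remaining k by T' and 'total time <= T' are one event."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(10, 500))
            T = float(rng.uniform(5, 60))
            P = float(rng.uniform(0.01, 1.0))
            m = int(rng.integers(0, n))
            Tm = float(rng.uniform(0, T))
            design = ap.StudyDesign(n, T, P)
            obs = make_obs(m, Tm)
            assert ap.completion_probability(design, obs) == pytest.approx(
                ap.on_time_probability(design, obs), abs=1e-9
            )


class TestDataSwamping:
    def test_prior_influence_vanishes_with_data(self):
        """With m >> nP and Tm >> TP the prior no longer moves the prediction."""
        m, Tm = 5000, 5000 * 0.15
        obs = make_obs(m, Tm)
        strong = ap.update_posterior(ap.StudyDesign(158, 24, 0.5), obs)
        weak = ap.update_posterior(ap.StudyDesign(158, 24, 0.001), obs)
        assert strong.r / (strong.r - m) > 60  # prior pseudo-count is now negligible
        for k in (10, 100):
            iv_s = ap.time_interval_exact(ap.TimePrediction(k=k, r=strong.r, s=strong.s))
            iv_w = ap.time_interval_exact(ap.TimePrediction(k=k, r=weak.r, s=weak.s))
            assert iv_s[0] == pytest.approx(iv_w[0], rel=0.02)
            assert iv_s[1] == pytest.approx(iv_w[1], rel=0.02)


class TestSamplePredictive:
    def test_count_mode_mean(self):
        state = ap.PosteriorState(r=79, s=12)
        draws = ap.sample_predictive(state, "count", window=24, n_draws=200_000, seed=11)
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 158.0) < 3 * se

    def test_time_mode_zero_remaining(self):
        state = ap.PosteriorState(r=79, s=12)
        draws = ap.sample_predictive(state, "time", k=0, n_draws=100, seed=1)
        assert np.all(draws == 0)

    def test_fixed_seed_reproduces_draws(self):
        state = ap.PosteriorState(r=79, s=12)
        a = ap.sample_predictive(state, "count", window=24, n_draws=1000, seed=42)
        b = ap.sample_predictive(state, "count", window=24, n_draws=1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            ap.sample_predictive(ap.PosteriorState(79, 12), "rate", n_draws=10)
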