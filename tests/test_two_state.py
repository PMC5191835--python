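"""Two-state model: sampling, moment inference, Gillespie simulation."""

import numpy as np
import pytest
from scipy import optimize, stats

from entrosurge.two_state import (
    EstimatorFailure,
    PoissonBetaParams,
    TrajectoryConfig,
    estimate_d0,
    fit_poisson_beta_moments,
    gillespie_trajectory,
    interp_rates,
    poisson_beta_sample,
    simulate_population,
)


def solve_moments_numerically(samples) -> tuple[float, float, float]:
    """Independent oracle: solve the three moment equations directly.

    r1 = c a/(a+b), r2 = c (a+1)/(a+b+1), r3 = c (a+2)/(a+b+2), solved with
    a generic nonlinear root finder instead of the closed form.
    """
    x = np.asarray(samples, dtype=float)
    e1 = x.mean()
    e2 = (x * (x - 1)).mean()
    e3 = (x * (x - 1) * (x - 2)).mean()
    r1, r2, r3 = e1, e2 / e1, e3 / e2

    def eqs(v):
        a, b, c = v
        return [
            c * a / (a + b) - r1,
            c * (a + 1) / (a + b + 1) - r2,
            c * (a + 2) / (a + b + 2) - r3,
        ]

    sol = optimize.fsolve(eqs, x0=[1.0, 1.0, max(r1 * 2, 1.0)], full_output=False, xtol=1e-13)
    return tuple(abs(v) for v in sol)


class TestPoissonBetaSampling:
    def test_sample_mean_matches_analytic_first_moment(self):
        p = PoissonBetaParams(1.0, 2.0, 100.0)
        x = poisson_beta_sample(p, 50000, seed=0)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - p.mean) < 4 * se

    def test_vanishing_scale_gives_all_zeros(self):
        x = poisson_beta_sample(PoissonBetaParams(1.0, 2.0, 1e-12), 500, seed=0)
        assert (x == 0).all()

    def test_on_dominated_limit_approaches_poisson(self):
        # a >> b and a >> 1: Z ~ 1, so X ~ Poisson(c) with variance/mean ~ 1
        x = poisson_beta_sample(PoissonBetaParams(500.0, 0.5, 50.0), 50000, seed=1)
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.1)

    def test_counts_are_nonnegative_integers(self):
        x = poisson_beta_sample(PoissonBetaParams(0.5, 0.5, 30.0), 1000, seed=2)
        assert x.dtype.kind == "i" and (x >= 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PoissonBetaParams(0.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            poisson_beta_sample(PoissonBetaParams(1, 1, 10), 0, seed=0)

    def test_rate_conversion_roundtrip(self):
        p = PoissonBetaParams.from_rates(kon=1.0, koff=2.0, s0=100.0, d0=0.5)
        assert (p.a, p.b, p.c) == (2.0, 4.0, 200.0)
        assert p.to_rates(0.5) == (1.0, 2.0, 100.0, 0.5)


class TestMomentEstimator:
    @pytest.mark.parametrize("a,b,c", [(1.0, 2.0, 100.0), (0.3, 1.0, 500.0), (3.0, 3.0, 50.0)])
    def test_closed_form_agrees_with_numerical_oracle(self, a, b, c):
        x = poisson_beta_sample(PoissonBetaParams(a, b, c), 5000, seed=42)
        fit = fit_poisson_beta_moments(x)
        a_n, b_n, c_n = solve_moments_numerically(x)
        assert fit.a == pytest.approx(a_n, rel=1e-6)
        assert fit.b == pytest.approx(b_n, rel=1e-6)
        assert fit.c == pytest.approx(c_n, rel=1e-6)

    def test_parameter_recovery_at_reference_point(self):
        true = PoissonBetaParams(1.0, 2.0, 100.0)
        errs = {"a": [], "b": [], "c": []}
        for seed in range(5):
            fit = fit_poisson_beta_moments(poisson_beta_sample(true, 20000, seed=seed))
            errs["a"].append(abs(fit.a - true.a) / true.a)
            errs["b"].append(abs(fit.b - true.b) / true.b)
            errs["c"].append(abs(fit.c - true.c) / true.c)
        assert np.median(errs["a"]) <= 0.25
        assert np.median(errs["b"]) <= 0.25
        assert np.median(errs["c"]) <= 0.10

    def test_refit_of_fitted_model_is_stable(self):
        x = poisson_beta_sample(PoissonBetaParams(1.0, 2.0, 100.0), 20000, seed=3)
        fit1 = fit_poisson_beta_moments(x)
        refits = [
            fit_poisson_beta_moments(poisson_beta_sample(fit1, 20000, seed=10 + s))
            for s in range(5)
        ]
        # drift of the closed loop stays within a small multiple of the
        # estimator's own spread
        for attr in ("a", "b", "c"):
            vals = np.array([getattr(f, attr) for f in refits])
            assert abs(vals.mean() - getattr(fit1, attr)) < 2 * max(vals.std(), 0.05 * getattr(fit1, attr))

    def test_scale_consistency_of_first_moment(self):
        # scaling c by k scales the sample mean by k
        base = poisson_beta_sample(PoissonBetaParams(1.0, 2.0, 100.0), 100000, seed=5)
        scaled = poisson_beta_sample(PoissonBetaParams(1.0, 2.0, 500.0), 100000, seed=5)
        assert scaled.mean() / base.mean() == pytest.approx(5.0, rel=0.05)

    def test_all_zero_samples_fail(self):
        with pytest.raises(EstimatorFailure):
            fit_poisson_beta_moments(np.zeros(100))

    def test_too_few_or_constant_samples_fail(self):
        with pytest.raises(EstimatorFailure):
            fit_poisson_beta_moments(np.arange(10))
        with pytest.raises(EstimatorFailure):
            fit_poisson_beta_moments(np.full(50, 7.0))


class TestGillespie:
    def test_pure_death_process_halves_at_ln2(self):
        anchors = [0.0, 10.0]
        rates = np.array([[0.0, 1.0, 0.0, 1.0]] * 2)  # s0 = 0, d0 = 1/h
        cfg = TrajectoryConfig(record_times=(np.log(2),), burn_in=0.0)
        ms = [
            gillespie_trajectory(anchors, rates, cfg, seed=s, m0=50, on0=0).mrna.iloc[0]
            for s in range(1000)
        ]
        ms = np.asarray(ms, dtype=float)
        se = ms.std() / np.sqrt(ms.size)
        assert abs(ms.mean() - 25.0) < 4 * se

    def test_stationary_marginal_is_poisson_beta(self):
        anchors = [0.0, 1.0]
        rates = np.array([[1.0, 2.0, 100.0, 1.0]] * 2)
        cfg = TrajectoryConfig(record_times=(0.0,), burn_in=100.0)
        ms = np.array(
            [gillespie_trajectory(anchors, rates, cfg, seed=s).mrna.iloc[0] for s in range(400)]
        )
        direct = poisson_beta_sample(PoissonBetaParams(1.0, 2.0, 100.0), 400, seed=99)
        assert stats.ks_2samp(ms, direct).pvalue > 0.01

    def test_interpolated_rates_at_midpoint_are_anchor_means(self):
        anchors = [0.0, 8.0]
        rates = np.array([[1.0, 2.0, 100.0, 1.0], [3.0, 6.0, 300.0, 1.0]])
        mid = interp_rates(anchors, rates, 4.0)
        assert np.allclose(mid, [2.0, 4.0, 200.0, 1.0])

    def test_rates_constant_before_onset_lag(self):
        anchors = [0.0, 8.0]
        rates = np.array([[1.0, 2.0, 100.0, 1.0], [3.0, 6.0, 300.0, 1.0]])
        assert np.allclose(interp_rates(anchors, rates, -50.0, lag=5.0), rates[0])
        assert np.allclose(interp_rates(anchors, rates, 4.0, lag=4.0), rates[0])
        # lagged cell at absolute time 9 h sits at schedule time 4 h
        assert np.allclose(interp_rates(anchors, rates, 9.0, lag=5.0), [2.0, 4.0, 200.0, 1.0])

    def test_trajectory_deterministic_for_fixed_seed(self):
        anchors = [0.0, 8.0]
        rates = np.array([[1.0, 2.0, 100.0, 1.0]] * 2)
        cfg = TrajectoryConfig(record_times=(0.0, 4.0, 8.0), burn_in=10.0)
        df1 = gillespie_trajectory(anchors, rates, cfg, seed=7)
        df2 = gillespie_trajectory(anchors, rates, cfg, seed=7)
        assert df1.equals(df2)

    def test_negative_rate_in_schedule_rejected(self):
        anchors = [0.0, 8.0]
        rates = np.array([[1.0, 2.0, -100.0, 1.0]] * 2)
        cfg = TrajectoryConfig(record_times=(1.0,))
        with pytest.raises(ValueError, match="negative"):
            gillespie_trajectory(anchors, rates, cfg, seed=0)


class TestSimulatePopulation:
    def test_zero_lag_async_equals_sync(self, constant_schedule):
        cfg = TrajectoryConfig(record_times=(0.0, 8.0), n_cells=5, burn_in=5.0, async_lag_max=0.0)
        m_sync = simulate_population(constant_schedule, cfg, "synchronous", seed=3)
        m_async = simulate_population(constant_schedule, cfg, "asynchronous", seed=3)
        assert m_sync.values.equals(m_async.values)

    def test_lags_recorded_in_metadata(self, constant_schedule):
        cfg = TrajectoryConfig(record_times=(0.0, 8.0), n_cells=6, burn_in=2.0, async_lag_max=24.0)
        m = simulate_population(constant_schedule, cfg, "asynchronous", seed=4)
        lags = m.cell_meta.loc[m.time_h == 0.0, "lag_h"]
        assert ((lags >= 0) & (lags <= 24.0)).all()
        assert lags.nunique() > 1

    def test_unknown_mode_rejected(self, constant_schedule):
        cfg = TrajectoryConfig(record_times=(0.0,), n_cells=2, burn_in=1.0)
        with pytest.raises(ValueError, match="mode"):
            simulate_population(constant_schedule, cfg, "diagonal", seed=0)


class TestEstimateD0:
    @pytest.mark.parametrize(
        "rate,times", [(0.5, [0, 1, 2, 4]), (np.log(2) / 2.0, [0, 2, 4, 6, 8])]
    )
    def test_exact_exponential_decay_recovered(self, rate, times):
        series = [(t, 100.0 * np.exp(-rate * t)) for t in times]
        assert estimate_d0(series) == pytest.approx(rate, rel=1e-9)

    def test_constant_series_gives_zero(self):
        assert estimate_d0([(0, 10.0), (1, 10.0), (2, 10.0)]) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_d0([(0, 1.0), (1, 0.5)])
        with pytest.raises(ValueError):
            estimate_d0([(0, 1.0), (1, 0.0), (2, 0.5)])
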