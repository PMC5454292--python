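import numpy as np
import pytest

from snorhythm.models import (COS12, COS24, LINEAR, EPS_FLOOR, CosineQParams,
                              LinearParams, cosineq_eval, l1_loglikelihood,
                              linear_eval, make_priors, model_mu)
from snorhythm.expression import TimeGrid, scale_series

from conftest import make_series


class TestCosineQ:
    @pytest.mark.parametrize("t,expected", [(0.0, 10.0), (12.0, 0.0)])
    def test_peak_and_trough(self, t, expected):
        params = CosineQParams(a=10, p=0, q=1, T=24)
        assert cosineq_eval(params, t) == pytest.approx(expected, abs=1e-12)

    def test_exponent_sharpening(self):
        assert cosineq_eval(CosineQParams(10, 0, 2, 24), 6.0) == pytest.approx(2.5)

    def test_range_and_period(self, rng):
        t = np.linspace(0, 48, 200)
        for _ in range(30):
            params = CosineQParams(a=rng.uniform(0, 10),
                                   p=rng.uniform(0, 2 * np.pi),
                                   q=rng.uniform(1, 8),
                                   T=float(rng.choice([24.0, 12.0])))
            f = cosineq_eval(params, t)
            assert np.all(f >= -1e-12) and np.all(f <= params.a + 1e-12)
            np.testing.assert_allclose(cosineq_eval(params, t + params.T), f,
                                       atol=1e-12)

    def test_peak_location_matches_phase(self, rng):
        for _ in range(10):
            params = CosineQParams(a=8, p=rng.uniform(0, 2 * np.pi), q=3, T=24)
            t = np.linspace(0, 24, 100001)
            t_peak = t[np.argmax(cosineq_eval(params, t))]
            assert t_peak == pytest.approx(params.phase_hours, abs=1e-3)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            CosineQParams(a=1, p=0, q=-0.5, T=24)


class TestLinear:
    def test_evaluation(self):
        assert linear_eval(LinearParams(0, 0.5), 20.0) == 10.0
        np.testing.assert_allclose(linear_eval(LinearParams(3, 0), np.arange(6)),
                                   3.0)

    def test_lad_fit_of_noiseless_line_is_the_line(self):
        times = np.arange(0, 24, 4.0)
        truth = LinearParams(2.0, 0.3)
        data = linear_eval(truth, times)
        b0s = np.linspace(0, 10, 201)
        b1s = np.linspace(-0.5, 0.5, 201)
        errs = np.abs(data[None, None, :]
                      - (b0s[:, None, None] + b1s[None, :, None] * times)).sum(-1)
        i, j = np.unravel_index(np.argmin(errs), errs.shape)
        assert b0s[i] == pytest.approx(truth.b0, abs=0.05)
        assert b1s[j] == pytest.approx(truth.b1, abs=0.005)


class TestL1Loglikelihood:
    ONE_TIME = TimeGrid((0.0,), 2)
    TWO_TIMES = TimeGrid((0.0, 4.0), 2)

    def test_single_time_closed_form(self):
        s = make_series([[1.0], [3.0]], grid=self.ONE_TIME)
        assert l1_loglikelihood(s, np.array([2.0])) == pytest.approx(
            -np.log(2.0), abs=1e-12)

    def test_two_time_closed_form(self):
        s = make_series([[0.0, 4.0], [2.0, 8.0]], grid=self.TWO_TIMES)
        expected = -np.log(2.0) + (-np.log(4.0) - 0.5)
        assert l1_loglikelihood(s, np.array([1.0, 5.0])) == pytest.approx(
            expected, abs=1e-12)

    def test_coincident_replicates_hit_floor(self):
        s = make_series([[2.0], [2.0]], grid=self.ONE_TIME)
        val = l1_loglikelihood(s, np.array([2.0]))
        assert np.isfinite(val)
        assert val == pytest.approx(-np.log(2 * EPS_FLOOR))

    def test_median_maximises_each_time_term(self, rng):
        # symmetric replicates: 1-D grid search over mu_t peaks at the median
        grid = TimeGrid((0.0,), 2)
        med, half = 4.0, 1.5
        s = make_series([[med - half], [med + half]], grid=grid)
        mus = np.linspace(0, 10, 2001)
        vals = [l1_loglikelihood(s, np.array([m])) for m in mus]
        assert mus[int(np.argmax(vals))] == pytest.approx(med, abs=0.01)

    def test_spread_scaling_downweights_by_log_c(self):
        grid = TimeGrid((0.0,), 2)
        med, d, c = 5.0, 0.8, 3.0
        tight = make_series([[med - d], [med + d]], grid=grid)
        wide = make_series([[med - c * d], [med + c * d]], grid=grid)
        mu = np.array([med])
        delta = l1_loglikelihood(tight, mu) - l1_loglikelihood(wide, mu)
        assert delta == pytest.approx(np.log(c), abs=1e-12)

    def test_missing_time_point_rejected(self):
        s = make_series([[np.nan], [np.nan]], grid=self.ONE_TIME)
        with pytest.raises(ValueError):
            l1_loglikelihood(s, np.array([1.0]))


class TestPriors:
    def test_cos24_primary_bounds(self):
        prior = make_priors(COS24)
        assert prior.names == ("a", "p", "q")
        np.testing.assert_allclose(prior.lower, [0.0, 0.0, 1.0])
        np.testing.assert_allclose(prior.upper, [10.0, 2 * np.pi, 8.0])

    def test_alternative_phase_window(self):
        prior = make_priors(COS12, phase_window="alternative")
        assert prior.lower[1] == pytest.approx(-np.pi)
        assert prior.upper[1] == pytest.approx(np.pi)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            make_priors("cos6")

    def test_linear_prior_bounds_follow_grid_span(self):
        prior = make_priors(LINEAR, grid_span_hours=20.0)
        np.testing.assert_allclose(prior.lower, [0.0, -0.5])
        np.testing.assert_allclose(prior.upper, [10.0, 0.5])

    def test_linear_prior_contains_lad_fit_of_scaled_lines(self, rng):
        # a scaled noiseless drift spans 0..10 over the grid, so its
        # least-absolute-deviation fit sits exactly on the prior boundary
        import statsmodels.api as sm
        prior = make_priors(LINEAR, grid_span_hours=20.0)
        times = np.arange(0, 24, 4.0)
        for _ in range(25):
            b0 = rng.uniform(2, 9)
            line = b0 + rng.uniform(-b0 / 25, 0.4) * times
            s = make_series(np.tile(line, (2, 1)))
            sc = scale_series(s)
            if sc.degenerate:
                continue
            y = sc.series.per_time_medians()
            b0, b1 = sm.QuantReg(y, sm.add_constant(times)).fit(q=0.5).params
            assert prior.lower[0] - 1e-6 <= b0 <= prior.upper[0] + 1e-6
            assert prior.lower[1] - 1e-6 <= b1 <= prior.upper[1] + 1e-6

    def test_model_mu_dispatches(self):
        times = np.array([0.0, 6.0])
        np.testing.assert_allclose(model_mu(COS24, [10, 0, 1], times), [10, 5])
        np.testing.assert_allclose(model_mu(LINEAR, [1, 0.5], times), [1, 4])
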