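"""Maximum-likelihood estimation of eta: oracles, round trips, intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egolayers import (
    ContinuumEgoModel,
    confidence_interval,
    continuum_cdf,
    empirical_cdf,
    fit_band,
    fit_ego,
    mean_normalized_cost,
    normalize_costs,
    sample_costs,
    solve_eta,
)
from egolayers.errors import DegenerateNetworkError, InsufficientDataError
from egolayers.estimation import bootstrap_confidence_interval, loglike

# frozen from a bisection oracle on E[t; eta] = 2/3 (xtol 1e-12)
ETA_AT_TWO_THIRDS = 2.1491257999


class TestNormalizeCosts:
    def test_hand_fixture(self, five_alter_network):
        costs = normalize_costs(five_alter_network)
        assert costs.sigma == pytest.approx(4.0)
        assert costs.t_bar == pytest.approx(2 / 3)
        assert np.allclose(np.sort(costs.t_values),
                           [0.0, 5 / 9, 8 / 9, 8 / 9, 1.0])

    def test_extremes_attained(self):
        costs = normalize_costs([7.0, 3.0, 2.0])
        assert costs.t_values.min() == 0.0 and costs.t_values.max() == 1.0

    def test_degenerate_equal_weights(self):
        with pytest.raises(DegenerateNetworkError):
            normalize_costs([3.0, 3.0, 3.0])

    def test_insufficient_alters(self):
        with pytest.raises(InsufficientDataError):
            normalize_costs([3.0])


class TestSolveEta:
    def test_symmetry_point_exact_zero(self):
        assert solve_eta(0.5) == 0.0

    def test_bisection_oracle_value(self):
        assert solve_eta(2 / 3) == pytest.approx(ETA_AT_TWO_THIRDS, abs=1e-6)

    @pytest.mark.parametrize("eta", [-10.0, -1.0, -0.1, 0.1, 2.0, 6.0, 10.0])
    def test_inverse_round_trip(self, eta):
        assert solve_eta(mean_normalized_cost(eta)) == pytest.approx(eta, abs=1e-6)

    @given(eta=st.floats(-20, 20))
    @settings(max_examples=60, deadline=None)
    def test_round_trip_property(self, eta):
        assert solve_eta(mean_normalized_cost(eta)) == pytest.approx(eta, abs=1e-6)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                solve_eta(bad)

    def test_bracket_expansion_beyond_default(self):
        # E[t] = 1 - 1/eta for large eta: t_bar = 0.995 needs eta ~ 200
        eta = solve_eta(0.995)
        assert eta > 50
        assert mean_normalized_cost(eta) == pytest.approx(0.995, abs=1e-9)


class TestMaximumLikelihoodIsMomentMatching:
    def test_grid_maximizer_matches_solver(self):
        # the likelihood of p(t) ∝ e^{eta t} peaks exactly where E[t] = t_bar
        rng = np.random.default_rng(2209)
        t = sample_costs(3.0, 40, rng)
        grid = np.linspace(-10, 15, 2501)
        ll = [loglike(e, t) for e in grid]
        best = grid[int(np.argmax(ll))]
        assert best == pytest.approx(solve_eta(t.mean()), abs=grid[1] - grid[0])


class TestConfidenceInterval:
    def test_contains_estimate(self, five_alter_network):
        costs = normalize_costs(five_alter_network)
        eta = solve_eta(costs.t_bar)
        lo, hi = confidence_interval(costs.t_values, eta, 0.025)
        assert lo <= eta <= hi

    @given(delta=st.sampled_from([-0.1, 0.0, 0.5, 0.7]))
    @settings(max_examples=4, deadline=None)
    def test_delta_domain(self, delta):
        with pytest.raises(ValueError):
            confidence_interval([0.0, 0.5, 1.0], 0.0, delta)

    def test_width_shrinks_as_root_L(self):
        # mean interval width at eta = 6 shrinks monotonically with L and
        # approaches the CLT 1/sqrt(L) rate once L is large; at small L the
        # convex inverse eta(t_bar) inflates the upper bound, so the exact
        # factor-2 ratio only emerges asymptotically
        rng = np.random.default_rng(990)
        widths = {}
        for L in (10, 40, 160, 640):
            w = []
            for _ in range(300):
                t = sample_costs(6.0, L, rng)
                eta = solve_eta(float(t.mean()))
                lo, hi = confidence_interval(t, eta, 0.025)
                w.append(hi - lo)
            widths[L] = np.mean(w)
        assert widths[10] > widths[40] > widths[160] > widths[640]
        assert widths[160] / widths[640] == pytest.approx(2.0, rel=0.10)

    def test_bootstrap_cross_check(self, five_alter_network):
        weights = list(five_alter_network.weights.values())
        lo, hi = bootstrap_confidence_interval(weights, seed=5, n_boot=500)
        eta = solve_eta(normalize_costs(weights).t_bar)
        assert lo < eta < hi


class TestFitEgo:
    def test_worked_example(self, five_alter_network):
        fit = fit_ego(five_alter_network)
        assert fit.eta_hat == pytest.approx(ETA_AT_TWO_THIRDS, abs=1e-6)
        assert fit.L == 5 and not fit.degenerate
        assert fit.eta_hat > 0
        # with only five alters the 95% interval straddles zero, so the
        # regime label is "boundary" despite the positive point estimate
        assert fit.ci_low < 0 < fit.ci_high
        assert fit.regime == "boundary"

    def test_below_partner_threshold_refused(self):
        from egolayers import EgoNetwork

        net = EgoNetwork(ego_id="x", group_id="g",
                         weights={"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        with pytest.raises(InsufficientDataError):
            fit_ego(net)

    def test_degenerate_network_is_flagged_not_fatal(self):
        from egolayers import EgoNetwork

        net = EgoNetwork(ego_id="x", group_id="g",
                         weights={a: 2.0 for a in "abcde"})
        fit = fit_ego(net)
        assert fit.degenerate and np.isnan(fit.eta_hat)
        assert fit.regime == "degenerate"

    def test_large_sample_truth_in_interval(self):
        # L = 200 exact draws at eta = 6: the fitted interval covers 6
        t = sample_costs(6.0, 200, seed=31)
        eta = solve_eta(float(t.mean()))
        lo, hi = confidence_interval(t, eta, 0.025)
        assert lo <= 6.0 <= hi


class TestModelResults:
    def test_statsmodels_style_surface(self, five_alter_network):
        res = ContinuumEgoModel(five_alter_network).fit()
        assert res.params[0] == pytest.approx(ETA_AT_TWO_THIRDS, abs=1e-6)
        assert res.conf_int()[0, 0] <= res.eta <= res.conf_int()[0, 1]
        assert res.nobs == 5
        assert "eta" in res.summary()
        record = res.as_record()
        assert record.eta_hat == pytest.approx(res.eta)
        assert record.ego_id == "A"

    def test_predict_is_model_cdf(self, five_alter_network):
        res = ContinuumEgoModel(five_alter_network).fit()
        t = np.linspace(0, 1, 9)
        assert np.allclose(res.predict(t), continuum_cdf(res.eta, t))

    def test_loglike_at_mle_beats_neighbours(self, five_alter_network):
        model = ContinuumEgoModel(five_alter_network)
        res = model.fit()
        assert model.loglike(res.eta) >= model.loglike(res.eta + 0.1)
        assert model.loglike(res.eta) >= model.loglike(res.eta - 0.1)

    def test_bootstrap_method(self, five_alter_network):
        res = ContinuumEgoModel(five_alter_network).fit(method="bootstrap",
                                                        seed=7, n_boot=300)
        assert res.ci_low < res.eta < res.ci_high


class TestEmpiricalCdf:
    def test_hand_fixture_with_tie(self, five_alter_network):
        points, fractions = empirical_cdf(normalize_costs(five_alter_network))
        assert np.allclose(points, [0.0, 5 / 9, 8 / 9, 1.0])
        assert np.allclose(fractions, [0.2, 0.4, 0.8, 1.0])

    def test_last_fraction_is_one(self):
        rng = np.random.default_rng(8)
        _, fractions = empirical_cdf(rng.uniform(size=17))
        assert fractions[-1] == pytest.approx(1.0)

    def test_attained_extremes_step_heights(self):
        points, fractions = empirical_cdf(np.array([0.0, 0.4, 1.0]))
        assert points[0] == 0.0 and fractions[0] == pytest.approx(1 / 3)


class TestFitBand:
    def _fit(self, eta, lo, hi):
        from egolayers import ContinuumFit

        return ContinuumFit(ego_id="x", group_id="g", L=10, n_follows=0,
                            sigma=1.0, t_bar=0.6, eta_hat=eta, ci_low=lo,
                            ci_high=hi, delta=0.025, regime="normal",
                            degenerate=False)

    def test_pinned_endpoints(self):
        lower, upper = fit_band(self._fit(6.0, 4.0, 9.0), [0.0, 1.0])
        assert np.allclose(lower, [0.0, 1.0]) and np.allclose(upper, [0.0, 1.0])

    def test_zero_width_interval_collapses(self):
        lower, upper = fit_band(self._fit(6.0, 6.0, 6.0), np.linspace(0, 1, 7))
        assert np.allclose(lower, upper)

    def test_monotone_envelope_hand_values(self):
        lower, upper = fit_band(self._fit(6.0, 4.0, 9.0), [0.5])
        assert lower[0] == pytest.approx(continuum_cdf(9.0, 0.5))
        assert upper[0] == pytest.approx(continuum_cdf(4.0, 0.5))
        assert lower[0] < continuum_cdf(6.0, 0.5) < upper[0]

    def test_degenerate_gives_empty_band(self):
        fit = self._fit(np.nan, np.nan, np.nan)
        fit.degenerate = True
        lower, upper = fit_band(fit, [0.2, 0.8])
        assert lower.size == 0 and upper.size == 0
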