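import itertools

import numpy as np
import pytest

from steppekit.arrival_model import (
    ArrivalParams,
    default_start,
    fit_arrival,
    model_curve,
    monte_carlo_arrival,
    rss_objective,
    sample_dates,
    weighted_kde,
)
from steppekit.io_tables import AncestryObservation, RadiocarbonInterval
from steppekit.synthetic_data import SimulationConfig, simulate_cohort

TRUTH = ArrivalParams(p0=0.1, pe=0.8, te=2750.0)

# a 50-point date grid that includes the jump itself, so the arrival time is
# point-identified in the noise-free limit
GRID_DATES = np.linspace(1750.0, 4200.0, 50)


class TestModelCurve:
    def test_jump_and_pre_arrival_values(self):
        assert model_curve(TRUTH.te, TRUTH) == pytest.approx(TRUTH.pe)
        assert model_curve(TRUTH.te + 1.0, TRUTH) == 0.0
        assert model_curve(0.0, TRUTH) == pytest.approx(TRUTH.p0)

    def test_closed_form_halfway_point(self):
        # pe * (p0/pe)^((te-t)/te) at t = te/2 -> 0.8 * 0.125^0.5
        assert model_curve(1375.0, TRUTH) == pytest.approx(0.8 * 0.125**0.5, rel=1e-12)

    def test_exponential_extends_to_ce_times(self):
        # negative calBCE (common era): same exponential, below p0
        assert 0.0 < model_curve(-100.0, TRUTH) < TRUTH.p0

    def test_monotone_nondecreasing_up_to_the_jump(self):
        t = np.linspace(0.0, TRUTH.te, 500)
        vals = np.asarray(model_curve(t, TRUTH))
        assert (np.diff(vals) >= 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ArrivalParams(p0=0.5, pe=0.2, te=2750.0)
        with pytest.raises(ValueError):
            ArrivalParams(p0=0.1, pe=0.8, te=-5.0)


class TestRssObjective:
    def test_noise_free_data_has_zero_rss(self):
        props = np.asarray(model_curve(GRID_DATES, TRUTH))
        rss, _ = rss_objective(TRUTH, props, GRID_DATES)
        assert rss == pytest.approx(0.0, abs=1e-20)

    def test_post_arrival_zero_is_masked(self):
        rss, masked = rss_objective(
            TRUTH, np.array([0.0]), np.array([TRUTH.te - 200.0])
        )
        assert rss == 0.0 and masked == 1

    def test_pre_arrival_nonzero_counts_against_zero_branch(self):
        rss, masked = rss_objective(
            TRUTH, np.array([0.5]), np.array([TRUTH.te + 100.0])
        )
        assert rss == pytest.approx(0.25) and masked == 0

    def test_mask_never_increases_rss(self, rng):
        for _ in range(50):
            params = ArrivalParams(
                p0=rng.uniform(0.01, 0.3),
                pe=rng.uniform(0.4, 1.0),
                te=rng.uniform(2000, 3500),
            )
            n = 30
            props = rng.uniform(0, 1, n)
            props[rng.random(n) < 0.3] = 0.0
            dates = rng.uniform(1700, 4800, n)
            with_rule, _ = rss_objective(params, props, dates, zero_tol=0.0)
            without_rule, _ = rss_objective(params, props, dates, zero_tol=-1.0)
            assert with_rule <= without_rule + 1e-12

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rss_objective(TRUTH, np.array([]), np.array([]))


class TestFitArrival:
    def test_default_start_uses_mean_nonzero_date(self):
        props = np.array([0.0, 0.5, 0.3, 0.0, 0.4])
        dates = np.array([4000.0, 2500.0, 2300.0, 3900.0, 2400.0])
        start = default_start(props, dates)
        assert (start.p0, start.pe) == (0.1, 0.8)
        assert start.te == pytest.approx(2400.0)

    def test_noise_free_recovery_matches_grid_search_oracle(self):
        """The optimizer's solution beats every point of a coarse lattice,
        whose argmin region brackets the generating parameters."""
        props = np.asarray(model_curve(GRID_DATES, TRUTH))
        fit = fit_arrival(props, GRID_DATES, seed=0)
        assert fit.converged and fit.hessian_pd
        assert fit.params.p0 == pytest.approx(TRUTH.p0, rel=1e-3)
        assert fit.params.pe == pytest.approx(TRUTH.pe, rel=1e-3)
        assert fit.params.te == pytest.approx(TRUTH.te, rel=1e-3)

        best_lattice, best_point = np.inf, None
        for p0, pe, te in itertools.product(
            np.linspace(0.05, 0.3, 6),
            np.linspace(0.5, 1.0, 6),
            np.linspace(2500, 3000, 11),
        ):
            if p0 > pe:
                continue
            rss, _ = rss_objective(ArrivalParams(p0, pe, te), props, GRID_DATES)
            if rss < best_lattice:
                best_lattice, best_point = rss, (p0, pe, te)
        assert fit.rss <= best_lattice + 1e-12
        assert abs(best_point[2] - TRUTH.te) <= 50.0  # lattice step

    def test_all_zero_proportions_unidentifiable(self):
        with pytest.raises(ValueError, match="nonzero"):
            fit_arrival(np.zeros(10), np.linspace(2000, 4000, 10))

    def test_zero_rule_restores_pe_when_zeros_cluster_near_the_jump(self):
        """Zero-ancestry individuals dated close to the arrival drag the
        fitted jump height down unless masked — the bias the rule targets."""
        rng = np.random.default_rng(0)
        for s in range(10):
            r = np.random.default_rng(s)
            d_nz = r.uniform(1700, 4800, 54)
            p_nz = np.asarray(model_curve(d_nz, TRUTH))
            d_z = r.uniform(2400, 2740, 6)  # post-arrival, near te
            dates = np.concatenate([d_nz, d_z])
            props = np.concatenate([p_nz, np.zeros(6)])
            with_rule = fit_arrival(props, dates, seed=1, use_zero_rule=True)
            without_rule = fit_arrival(props, dates, seed=1, use_zero_rule=False)
            assert with_rule.params.pe >= without_rule.params.pe - 1e-9
            # zeros dated below the fitted jump are masked; any dated above
            # it sit on the zero branch and need no masking
            assert with_rule.n_zero_masked >= 1


class TestSampleDates:
    def intervals(self, n, upper=2860.0, lower=2460.0):
        return [RadiocarbonInterval(upper, lower)] * n

    def test_draws_respect_truncation_bounds(self, rng):
        draws = sample_dates(self.intervals(5000), rng)
        assert draws.min() >= 2460.0 and draws.max() <= 2860.0

    def test_symmetric_truncation_preserves_the_midpoint(self, rng):
        draws = sample_dates(self.intervals(100_000), rng)
        assert abs(draws.mean() - 2660.0) <= 3.0

    def test_interval_sd_matches_95pct_convention(self, rng):
        # sd before truncation is width / (2 * 1.96); truncation shrinks it
        draws = sample_dates(self.intervals(100_000), rng)
        sd_untruncated = 400.0 / (2 * 1.959964)
        assert draws.std() < sd_untruncated
        assert draws.std() > 0.8 * sd_untruncated

    def test_zero_width_interval_returns_point_date(self, rng):
        draws = sample_dates([RadiocarbonInterval(2500.0, 2500.0)] * 3, rng)
        assert (draws == 2500.0).all()


class TestWeightedKde:
    def test_equal_weights_match_unweighted(self, rng):
        x = rng.normal(0, 1, 200)
        g1, d1 = weighted_kde(x)
        g2, d2 = weighted_kde(x, np.full(200, 7.0))  # scale-invariant weights
        np.testing.assert_allclose(d1, d2)

    def test_dominant_weight_sets_the_mode(self):
        grid, dens = weighted_kde(
            [2700.0, 2500.0], [1.0, 1e-9], bandwidth=30.0
        )
        assert abs(grid[np.argmax(dens)] - 2700.0) < 5.0

    def test_density_integrates_to_one(self, rng):
        grid, dens = weighted_kde(rng.normal(0, 1, 500), rng.uniform(0.1, 1, 500))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_sample_density_is_flat_in_the_interior(self, rng):
        x = rng.uniform(0, 1, 10_000)
        grid, dens = weighted_kde(x)
        interior = dens[(grid >= 0.2) & (grid <= 0.8)]
        assert (np.abs(interior - 1.0) < 0.1).all()

    def test_degenerate_sample_needs_explicit_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            weighted_kde([5.0, 5.0, 5.0])
        grid, dens = weighted_kde([5.0, 5.0, 5.0], bandwidth=1.0)
        assert abs(grid[np.argmax(dens)] - 5.0) < 0.1


class TestMonteCarlo:
    def make_cohort(self, width, n=40, seed=0, noise=0.05):
        cfg = SimulationConfig(
            n_individuals=n, noise_sd=noise, zero_ancestry_fraction=0.0,
            interval_width_range=(width, width), true_params=TRUTH, seed=seed,
        )
        records, observations, _ = simulate_cohort(cfg)
        return [observations[r.id] for r in records], [r.date for r in records]

    def test_zero_width_intervals_reduce_to_the_deterministic_fit(self):
        obs, intervals = self.make_cohort(width=0.0, noise=0.0)
        est = monte_carlo_arrival(obs, intervals, n_reps=10, seed=1)
        assert len(np.unique(est.te_samples)) == 1
        np.testing.assert_allclose(est.weights, 1.0)
        props = np.array([o.steppe_prop for o in obs])
        dates = np.array([iv.midpoint for iv in intervals])
        det = fit_arrival(props, dates, seed=1)
        assert est.te_samples[0] == pytest.approx(det.params.te, abs=1e-6)

    def test_retained_count_bounded_and_weights_normalised(self):
        obs, intervals = self.make_cohort(width=200.0)
        est = monte_carlo_arrival(obs, intervals, n_reps=40, seed=2)
        assert len(est.te_samples) <= 40
        assert est.weights.max() == pytest.approx(1.0)
        assert (est.weights > 0).all()

    def test_bitwise_reproducible_under_fixed_seed(self):
        obs, intervals = self.make_cohort(width=200.0)
        a = monte_carlo_arrival(obs, intervals, n_reps=30, seed=3)
        b = monte_carlo_arrival(obs, intervals, n_reps=30, seed=3)
        assert np.array_equal(a.te_samples, b.te_samples)
        assert np.array_equal(a.weights, b.weights)
        assert a.point_estimate == b.point_estimate

    def test_estimate_interval_widens_with_dating_uncertainty(self):
        narrow_obs, narrow_iv = self.make_cohort(width=50.0, seed=5)
        wide_obs, wide_iv = self.make_cohort(width=400.0, seed=5)
        narrow = monte_carlo_arrival(narrow_obs, narrow_iv, n_reps=60, seed=4)
        wide = monte_carlo_arrival(wide_obs, wide_iv, n_reps=60, seed=4)
        assert (wide.interval[1] - wide.interval[0]) > (
            narrow.interval[1] - narrow.interval[0]
        )

    def test_scaled_weight_mode_downweights_harder(self):
        obs, intervals = self.make_cohort(width=200.0)
        lit = monte_carlo_arrival(obs, intervals, n_reps=30, seed=6)
        sca = monte_carlo_arrival(
            obs, intervals, n_reps=30, seed=6, weight_mode="scaled"
        )
        # same retained solutions, sharper weight contrast
        assert np.array_equal(lit.te_samples, sca.te_samples)
        assert sca.weights.min() <= lit.weights.min() + 1e-12
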