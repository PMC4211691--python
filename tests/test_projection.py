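import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from espanola._rand import substream
from espanola.projection import (
    ProjectionConfig,
    Scenario,
    VitalRateBounds,
    draw_parameter_set,
    estimate_fertility_product,
    euler_lotka_lambda,
    leslie_lambda,
    run_scenario,
    simulate_population,
    total_fertility,
)

MID_RATES = {
    "age_first_reproduction": 17, "proportion_female": 0.5,
    "eggs_per_female": 7.0, "hatching_success": 0.205,
    "hatchling_survival": 0.205, "survival_age_1_3": 0.75,
    "phi_juvenile": 0.958, "phi_adult": 0.977,
    "carrying_capacity": 1e9,
}


class TestParameterDraws:
    def test_degenerate_bounds_return_bound(self):
        cfg = ProjectionConfig()
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert draw_parameter_set(cfg, rng)["age_first_reproduction"] == 17

    def test_uniform_mean_of_eggs(self):
        cfg = ProjectionConfig()
        rng = np.random.default_rng(1)
        draws = [draw_parameter_set(cfg, rng)["eggs_per_female"]
                 for _ in range(10000)]
        se = (10 - 4) / math.sqrt(12) / math.sqrt(10000)
        assert abs(np.mean(draws) - 7.0) < 3 * se

    def test_fertility_components_perfectly_rank_correlated(self):
        cfg = ProjectionConfig()
        rng = np.random.default_rng(2)
        draws = [draw_parameter_set(cfg, rng) for _ in range(200)]
        eggs = [d["eggs_per_female"] for d in draws]
        for other in ("proportion_female", "hatching_success",
                      "hatchling_survival"):
            rho = spearmanr(eggs, [d[other] for d in draws]).statistic
            assert rho == pytest.approx(1.0)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            ProjectionConfig(bounds=VitalRateBounds(eggs_per_female=(10, 4)))


class TestFertility:
    def test_direct_product(self):
        rates = {"proportion_female": 0.5, "eggs_per_female": 7,
                 "hatching_success": 0.15, "hatchling_survival": 0.15}
        assert total_fertility(rates) == pytest.approx(0.07875)

    def test_any_zero_component_annihilates(self):
        rates = {"proportion_female": 0.5, "eggs_per_female": 0,
                 "hatching_success": 0.2, "hatchling_survival": 0.2}
        assert total_fertility(rates) == 0

    def test_hatching_product_bounds(self):
        # the egg-viability x hatchling-survival product spans 0.0225-0.0676
        assert 0.15 * 0.15 == pytest.approx(0.0225)
        lo = total_fertility({"proportion_female": 1, "eggs_per_female": 1,
                              "hatching_success": 0.15,
                              "hatchling_survival": 0.15})
        hi = total_fertility({"proportion_female": 1, "eggs_per_female": 1,
                              "hatching_success": 0.26,
                              "hatchling_survival": 0.26})
        assert lo == pytest.approx(0.0225) and hi == pytest.approx(0.0676)


class TestSimulation:
    def _config(self, **kw):
        defaults = dict(horizon_years=20, temporal_sd_logit=0.0, seed=0,
                        replicates=5)
        defaults.update(kw)
        return ProjectionConfig(**defaults)

    def test_conservation_with_no_mortality_no_recruitment(self):
        cfg = self._config()
        rates = {**MID_RATES, "survival_age_1_3": 1.0, "phi_juvenile": 1.0,
                 "phi_adult": 1.0, "eggs_per_female": 0.0}
        init = np.zeros(cfg.max_age, dtype=int)
        init[[3, 10, 20]] = [50, 30, 20]
        tr = simulate_population(rates, cfg, np.random.default_rng(1),
                                 initial=init)
        assert (tr.total_females == 100).all()

    def test_zero_fertility_is_non_increasing(self):
        cfg = self._config()
        rates = {**MID_RATES, "eggs_per_female": 0.0}
        init = np.full(cfg.max_age, 10, dtype=int)
        tr = simulate_population(rates, cfg, np.random.default_rng(2),
                                 initial=init)
        assert (np.diff(tr.total_females) <= 0).all()

    def test_mean_trajectory_matches_leslie_expectation(self):
        cfg = self._config(horizon_years=5)
        rates = dict(MID_RATES)
        A = cfg.max_age
        init = np.zeros(A, dtype=int)
        init[[5, 16, 19, 25]] = [100, 50, 80, 70]

        # deterministic expectation via the same yearly update in means
        expected = init.astype(float)
        for _ in range(5):
            s = np.where(np.arange(1, A + 1) <= 3, rates["survival_age_1_3"],
                         np.where(np.arange(1, A + 1) < cfg.juvenile_age_max,
                                  rates["phi_juvenile"], rates["phi_adult"]))
            surv = expected * s
            breeders = surv[np.arange(1, A + 1) >= 17].sum()
            nxt = np.zeros(A)
            nxt[1:] = surv[:-1]
            nxt[A - 1] += surv[A - 1]
            nxt[0] = breeders * total_fertility(rates)
            expected = nxt

        n_rep = 4000
        totals = np.zeros(n_rep)
        for r in range(n_rep):
            tr = simulate_population(rates, cfg, np.random.default_rng(r),
                                     initial=init)
            totals[r] = tr.total_females[5]
        se = totals.std(ddof=1) / math.sqrt(n_rep)
        assert abs(totals.mean() - expected.sum()) < 3 * se

    def test_ceiling_binds_every_year(self):
        cfg = self._config(horizon_years=30)
        rates = {**MID_RATES, "carrying_capacity": 150.0,
                 "eggs_per_female": 10, "hatching_success": 0.26,
                 "hatchling_survival": 0.26, "proportion_female": 0.7}
        init = np.full(cfg.max_age, 10, dtype=int)
        tr = simulate_population(rates, cfg, np.random.default_rng(3),
                                 initial=init)
        # the ceiling binds from the first annual step onward
        assert (tr.total_females[1:] <= 150).all()

    def test_negative_initial_rejected(self):
        cfg = self._config()
        init = np.zeros(cfg.max_age, dtype=int)
        init[0] = -1
        with pytest.raises(ValueError):
            simulate_population(MID_RATES, cfg, np.random.default_rng(0),
                                initial=init)

    def test_replicates_reproducible_under_seed(self):
        cfg = ProjectionConfig(horizon_years=30, replicates=3, seed=9)
        a = run_scenario(cfg, "terminate")
        b = run_scenario(cfg, "terminate")
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.counts, tb.counts)


class TestScenarioRisk:
    def test_unreachable_threshold_gives_zero_probability(self):
        cfg = ProjectionConfig(
            bounds=VitalRateBounds(survival_age_1_3=(1.0, 1.0)),
            phi_juvenile=1.0, phi_adult=1.0, temporal_sd_logit=0.0,
            quasi_extinction_adults=0, replicates=10, horizon_years=30,
            seed=3)
        assert run_scenario(cfg, "terminate").extirpation_probability == 0.0

    def test_threshold_above_initial_population_hits_immediately(self):
        cfg = ProjectionConfig(quasi_extinction_adults=5000, replicates=10,
                               horizon_years=10, seed=4)
        assert run_scenario(cfg, "terminate").extirpation_probability == 100.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            run_scenario(ProjectionConfig(replicates=2, horizon_years=5),
                         "eradicate")


class TestGrowthRate:
    def test_zero_fertility_reduces_to_adult_survival(self):
        rates = {**MID_RATES, "eggs_per_female": 0.0}
        assert leslie_lambda(rates) == pytest.approx(0.977, abs=1e-9)
        assert euler_lotka_lambda(rates) == pytest.approx(0.977, abs=1e-6)

    def test_supercritical_with_perfect_survival(self):
        rates = {**MID_RATES, "survival_age_1_3": 1.0, "phi_juvenile": 1.0,
                 "phi_adult": 1.0}
        assert leslie_lambda(rates) > 1.0

    def test_matrix_and_euler_lotka_agree(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            rates = {
                "age_first_reproduction": int(rng.integers(5, 25)),
                "proportion_female": rng.uniform(0.3, 0.7),
                "eggs_per_female": rng.uniform(4, 10),
                "hatching_success": rng.uniform(0.1, 0.3),
                "hatchling_survival": rng.uniform(0.1, 0.3),
                "survival_age_1_3": rng.uniform(0.6, 0.9),
                "phi_juvenile": rng.uniform(0.85, 0.99),
                "phi_adult": rng.uniform(0.9, 0.995),
            }
            assert abs(leslie_lambda(rates)
                       - euler_lotka_lambda(rates)) < 1e-8


class TestFertilityEstimator:
    def test_recovers_generating_product(self):
        from espanola.projection import native_fraction_path

        truth_g = 0.04
        path, years = native_fraction_path(truth_g)
        obs_years = [y for y in range(2000, 2008)]
        grid = np.linspace(0.005, 0.12, 47)
        hits = 0
        for seed in range(20):
            rng = substream(seed, "fert_obs")
            obs = {y: float(np.clip(path[int(y - years[0])]
                                    + rng.normal(0, 0.01), 0, 1))
                   for y in obs_years}
            res = estimate_fertility_product(obs, grid=grid)
            lo, hi = res["interval"]
            hits += (lo - 1e-9) <= truth_g <= (hi + 1e-9)
        assert hits >= 18

    def test_no_signal_abuts_grid_minimum(self):
        grid = np.linspace(0.005, 0.12, 24)
        res = estimate_fertility_product({y: 0.0 for y in range(2000, 2008)},
                                         grid=grid)
        assert res["interval"][0] == pytest.approx(grid[0])

    def test_component_mapping_via_square_root(self):
        grid = np.array([0.0225, 0.04])
        res = estimate_fertility_product({2000: 0.0}, grid=grid)
        assert res["per_component"][0] == pytest.approx(
            math.sqrt(res["interval"][0]))

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            estimate_fertility_product({})
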