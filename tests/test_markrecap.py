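import numpy as np
import pandas as pd
import pytest

from espanola.markrecap import (
    CjsConfig,
    CjsPosterior,
    build_m_array,
    cjs_log_likelihood,
    derive_abundance,
    filter_growth_records,
    fit_cjs_mcmc,
    gelman_rubin,
)
from espanola.synthetic import SimulationTruth, gen_capture_histories

from _oracles import latent_path_loglik
from conftest import random_capture_table


class TestGrowthFiltering:
    def test_empty_input(self):
        df = pd.DataFrame(columns=["interval_years", "growth_cm_per_year"])
        assert filter_growth_records(df).empty

    def test_long_intervals_removed_before_trimming(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "interval_years": [1.0] * 38 + [4.0, 4.0],
            "growth_cm_per_year": rng.normal(3, 1, 40),
        })
        out = filter_growth_records(df)
        assert (out["interval_years"] <= 3).all()
        assert len(out) == 38  # floor(0.025 * 38) = 0 trimmed

    def test_matches_brute_force_sort_and_slice(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "interval_years": rng.uniform(0.5, 3.0, 200),
            "growth_cm_per_year": rng.normal(3, 2, 200),
        })
        out = filter_growth_records(df)
        vals = np.sort(df["growth_cm_per_year"].to_numpy())
        k = int(np.floor(0.025 * 200))
        expected = vals[k:200 - k]
        assert np.allclose(np.sort(out["growth_cm_per_year"]), expected)


class TestMArray:
    def test_hand_tabulated_example(self, tiny_capture_table):
        ma = build_m_array(tiny_capture_table, excluded_years=())
        rows = {(int(o), int(a), bool(n)): i for i, (o, a, n) in
                enumerate(zip(ma.cohort_occ, ma.cohort_age, ma.cohort_new))}
        # release cohort 2000 age 3: A first seen 2002, B first seen 2001
        r = rows[(0, 3, True)]
        assert ma.m[r, 2] == 1 and ma.m[r, 1] == 1 and ma.never[r] == 0
        # A re-enters 2002 at age 5, never seen again
        assert ma.never[rows[(2, 5, False)]] == 1
        # B re-enters 2001 age 4 -> seen 2003; re-enters 2003 age 6 -> never
        assert ma.m[rows[(1, 4, False)], 3] == 1
        assert ma.never[rows[(3, 6, False)]] == 1
        # C released 2000 age 7 never seen
        assert ma.never[rows[(0, 7, True)]] == 1
        # D, E release cohort 2001 age 3: one first recapture 2002, one never
        r2 = rows[(1, 3, True)]
        assert ma.m[r2, 2] == 1 and ma.never[r2] == 1

    def test_cohort_rows_conserve_releases(self):
        rng = np.random.default_rng(2)
        tab = random_capture_table(rng, 60, range(2000, 2006))
        ma = build_m_array(tab, excluded_years=())
        # every entry (release or re-release) is accounted for exactly once
        n_entries = len(tab) + tab[[f"y{y}" for y in range(2000, 2006)]].to_numpy().sum()
        assert ma.released.sum() == n_entries
        assert (ma.released == ma.m.sum(axis=1) + ma.never).all()

    def test_detection_before_release_rejected(self):
        tab = pd.DataFrame([{
            "individual_id": "bad", "release_year": 2002,
            "release_site": "tunas", "age_at_release": 3, "native_born": 0,
            "y2000": 1, "y2001": 0, "y2002": 0,
        }])
        with pytest.raises(ValueError, match="bad"):
            build_m_array(tab, excluded_years=())


class TestLikelihood:
    def test_certain_history_has_zero_loglik(self, tiny_capture_table):
        tab = tiny_capture_table.copy()
        for y in range(2001, 2004):
            tab.loc[tab["release_year"] < y, f"y{y}"] = 1
        # fix histories: everyone detected every year after release
        tab.loc[tab["release_year"] == 2001, "y2001"] = 0
        ma = build_m_array(tab, excluded_years=())
        ll = cjs_log_likelihood({"phi_release": 1, "phi_juvenile": 1,
                                 "phi_adult": 1, "p_young": 1, "p_adult": 1},
                                ma)
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_latent_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        years = range(2000, 2000 + int(rng.integers(3, 6)))
        tab = random_capture_table(rng, int(rng.integers(2, 7)), years)
        params = {"phi_release": rng.uniform(0.3, 0.95),
                  "phi_juvenile": rng.uniform(0.5, 0.99),
                  "phi_adult": rng.uniform(0.5, 0.99),
                  "p_young": rng.uniform(0.2, 0.9),
                  "p_adult": rng.uniform(0.2, 0.9)}
        ma = build_m_array(tab, excluded_years=())
        ll = cjs_log_likelihood(params, ma)
        oracle = latent_path_loglik(tab, params, years)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_equals_latent_path_with_excluded_years(self):
        rng = np.random.default_rng(99)
        years = list(range(2000, 2006))
        tab = random_capture_table(rng, 6, years)
        tab[["y2002", "y2003"]] = 0  # no effort in excluded years
        params = {"phi_release": 0.8, "phi_juvenile": 0.9, "phi_adult": 0.95,
                  "p_young": 0.4, "p_adult": 0.35}
        ma = build_m_array(tab, excluded_years=(2002, 2003))
        oracle = latent_path_loglik(tab, params, years,
                                    excluded=(2002, 2003))
        assert cjs_log_likelihood(params, ma) == pytest.approx(oracle, abs=1e-10)

    def test_invalid_probability_rejected(self, tiny_capture_table):
        ma = build_m_array(tiny_capture_table, excluded_years=())
        with pytest.raises(ValueError):
            cjs_log_likelihood({"phi_adult": 1.2, "p_young": 0.5,
                                "p_adult": 0.5}, ma)

    def test_truth_beats_perturbations(self):
        truth = SimulationTruth(seed=5)
        sched = pd.DataFrame({"year": [2000, 2002, 2004],
                              "site": ["tunas"] * 3, "count": [300, 300, 300]})
        tab = gen_capture_histories(truth, sched,
                                    survey_years=range(2000, 2015),
                                    excluded_years=())
        ma = build_m_array(tab, excluded_years=())
        base = {"phi_release": truth.survival_release_year,
                "phi_juvenile": truth.survival_juvenile,
                "phi_adult": truth.survival_adult,
                "p_young": truth.capture_mean_young,
                "p_adult": truth.capture_mean_adult}
        ll_truth = cjs_log_likelihood(base, ma)
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(50):
            pert = {k: float(np.clip(v + rng.uniform(-0.2, 0.2), 0.01, 0.99))
                    for k, v in base.items()}
            wins += ll_truth >= cjs_log_likelihood(pert, ma)
        assert wins >= 45


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(7)
        c = rng.normal(size=5000)
        r = gelman_rubin(np.stack([c, c, c]))
        assert r[0] == pytest.approx(1.0, abs=1e-3)

    def test_stationary_chains_converged(self):
        rng = np.random.default_rng(8)
        chains = rng.normal(size=(3, 5000))
        assert gelman_rubin(chains)[0] < 1.1

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(9)
        chains = np.stack([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])
        assert gelman_rubin(chains)[0] > 2

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


def _point_posterior(phi_r, phi_j, phi_a, years):
    """Posterior with a single degenerate draw, for closed-form checks."""
    occ = np.arange(years[0], years[-1] + 1)
    one = np.ones((1, 1))
    return CjsPosterior(
        occasions=occ, release_years=[int(years[0])],
        phi_release=one * phi_r, phi_juvenile=one * phi_j,
        phi_adult=one * phi_a,
        p_young=np.array([0.4]), p_adult=np.array([0.4]),
        sigma_p=np.array([0.1]), eps=np.zeros((1, 0)),
        active_occasions=occ[1:], rhat={},
        exposure={"release": np.ones(1), "juvenile": np.ones(1),
                  "adult": np.ones(1)},
        config=CjsConfig(juvenile_block_years=1000, adult_block_years=1000),
    )


class TestAbundance:
    def test_no_mortality_equals_cumulative_releases(self):
        post = _point_posterior(1.0, 1.0, 1.0, (2000, 2005))
        sched = pd.DataFrame({"year": [2000, 2003], "site": ["tunas", "caco"],
                              "count": [100, 50]})
        est = derive_abundance(post, sched)
        arr = est.draws["tunas_caco"][0]
        assert np.allclose(arr, [100, 100, 100, 150, 150, 150])

    def test_closed_form_cohort_product(self):
        post = _point_posterior(0.5, 0.9, 0.95, (2000, 2003))
        sched = pd.DataFrame({"year": [2000], "site": ["tunas"],
                              "count": [100]})
        est = derive_abundance(post, sched, release_age=4)
        # 100 * 0.5 (release year) * 0.9 * 0.9 (juvenile at ages 5, 6)
        assert est.draws["tunas_caco"][0, 3] == pytest.approx(40.5)

    def test_matches_individual_forward_simulation(self):
        post = _point_posterior(0.7, 0.92, 0.97, (2000, 2010))
        sched = pd.DataFrame({"year": [2000], "site": ["tunas"],
                              "count": [200]})
        est = derive_abundance(post, sched, release_age=5)
        rng = np.random.default_rng(10)
        n_sim = 10000
        alive_by_year = np.zeros(11)
        for _ in range(n_sim):
            alive = True
            age = 5
            alive_by_year[0] += 1
            for t in range(10):
                phi = 0.7 if t == 0 else (0.92 if age < 8 else 0.97)
                if rng.random() >= phi:
                    alive = False
                    break
                age += 1
                alive_by_year[t + 1] += 1
        sim = alive_by_year / n_sim * 200
        expected = est.draws["tunas_caco"][0]
        se = 200 * np.sqrt(0.5 * 0.5 / n_sim)
        assert np.all(np.abs(sim - expected) < 3 * np.maximum(se, 0.5))

    def test_never_exceeds_cumulative_releases(self):
        post = _point_posterior(0.9, 0.95, 0.99, (2000, 2006))
        sched = pd.DataFrame({"year": [2000, 2002], "site": ["tunas"] * 2,
                              "count": [80, 40]})
        est = derive_abundance(post, sched)
        cum = np.array([80, 80, 120, 120, 120, 120, 120])
        assert np.all(est.draws["tunas_caco"][0] <= cum + 1e-9)

    def test_schedule_year_mismatch_rejected(self):
        post = _point_posterior(1, 1, 1, (2000, 2003))
        sched = pd.DataFrame({"year": [1990], "site": ["tunas"], "count": [5]})
        with pytest.raises(ValueError):
            derive_abundance(post, sched)


class TestMcmcFit:
    def test_saturated_detection_concentrates_capture_posterior(self):
        truth = SimulationTruth(capture_mean_young=1.0, capture_mean_adult=1.0,
                                capture_sd_logit=0.0, seed=11)
        sched = pd.DataFrame({"year": [2000, 2001], "site": ["tunas"] * 2,
                              "count": [150, 150]})
        tab = gen_capture_histories(truth, sched,
                                    survey_years=range(2000, 2010),
                                    excluded_years=())
        cfg = CjsConfig(chains=1, burn_in=400, iterations=400, thin=2,
                        excluded_years=frozenset(), seed=0)
        post = fit_cjs_mcmc(tab, cfg)
        assert np.mean(post.p_young > 0.95) > 0.9

    def test_no_recaptures_warns_not_crashes(self):
        truth = SimulationTruth(survival_release_year=0.0, seed=12)
        sched = pd.DataFrame({"year": [2000], "site": ["tunas"],
                              "count": [60]})
        tab = gen_capture_histories(truth, sched,
                                    survey_years=range(2000, 2005),
                                    excluded_years=())
        cfg = CjsConfig(chains=1, burn_in=100, iterations=100, thin=2,
                        excluded_years=frozenset(), seed=0)
        with pytest.warns(UserWarning, match="inestimable"):
            post = fit_cjs_mcmc(tab, cfg)
        assert post.inestimable

    def test_chains_agree_on_moderate_data(self):
        truth = SimulationTruth(seed=13)
        sched = pd.DataFrame({"year": [2000, 2001, 2002],
                              "site": ["tunas"] * 3, "count": [150] * 3})
        tab = gen_capture_histories(truth, sched,
                                    survey_years=range(2000, 2012),
                                    excluded_years=())
        cfg = CjsConfig(chains=2, burn_in=800, iterations=800, thin=4,
                        excluded_years=frozenset(), seed=1)
        post = fit_cjs_mcmc(tab, cfg)
        # draws stay probabilities and the two chains see the same posterior
        for draws in (post.phi_adult, post.phi_juvenile, post.p_young[:, None]):
            assert ((draws >= 0) & (draws <= 1)).all()
        informative = post.exposure["adult"] > 100
        assert np.nanmax(post.rhat["phi_adult"][informative]) < 1.3
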