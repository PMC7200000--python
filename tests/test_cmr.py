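"""Data augmentation bookkeeping, posterior summaries, sampler
correctness against exhaustive enumeration, and the Huggins estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, comb

from gartergen import (
    CaptureDataset,
    CaptureSimConfig,
    CmrConfig,
    build_augmented_data,
    covariate_evidence,
    fit_cmr,
    hpdi,
    huggins_fit,
    na_sexratio_regression,
    posterior_mode,
    sex_ratio_posterior,
    simulate_capture_histories,
)
from gartergen.cmr import CmrError, constant_p_config, read_capture_csvs


class TestAugmentation:
    def test_pool_bookkeeping(self, small_capture_dataset):
        aug = build_augmented_data(small_capture_dataset, 10)
        assert aug.m_total == 10
        assert aug.n_observed == 3
        assert (aug.y[3:] == 0).all()
        assert (aug.site_index[3:] == -1).all()

    def test_large_single_site_pool(self):
        """555 observed histories + 2000 pseudo-histories -> pool 2555."""
        rng = np.random.default_rng(0)
        y = np.zeros((555, 5), dtype=np.int8)
        y[np.arange(555), rng.integers(0, 5, 555)] = 1
        ds = CaptureDataset(
            site="big",
            occasions=[f"2017-04-{d + 1:02d}" for d in range(5)],
            air_temp=np.full(5, 15.0),
            individuals=pd.DataFrame(
                {
                    "individual_id": [f"x{k}" for k in range(555)],
                    "sex": ["F", "M"] * 277 + ["U"],
                    "svl_mm": np.full(555, 450.0),
                }
            ),
            captures=y,
        )
        aug = build_augmented_data(ds, 555 + 2000)
        assert aug.m_total == 2555

    def test_multi_site_pool_of_1000(self):
        datasets = []
        for k in range(5):
            sim = CaptureSimConfig(n_true=30, n_occasions=4, p_intercept=0.4,
                                   site=f"s{k}", seed=k)
            ds, _ = simulate_capture_histories(sim)
            datasets.append(ds)
        aug = build_augmented_data(datasets, 1000)
        assert aug.m_total == 1000
        assert len(aug.sites) == 5

    def test_zero_pseudo_rows(self, small_capture_dataset):
        aug = build_augmented_data(small_capture_dataset, 3)
        assert aug.n_observed == aug.m_total == 3

    def test_pool_below_observed_errors(self, small_capture_dataset):
        with pytest.raises(CmrError):
            build_augmented_data(small_capture_dataset, 2)

    def test_behavior_covariate_lags_observed_captures(self, small_capture_dataset):
        aug = build_augmented_data(small_capture_dataset, 5)
        assert (aug.behavior[:, 0] == 0).all()  # first occasion
        assert (aug.behavior[:3, 1] == small_capture_dataset.captures[:, 0]).all()

    def test_covariate_standardization_from_observed(self, small_capture_dataset):
        aug = build_augmented_data(small_capture_dataset, 8)
        obs_svl = aug.svl_z[:3]
        assert obs_svl.mean() == pytest.approx(0.0, abs=1e-9)


class TestSummaries:
    def test_mode_tie_toward_smaller(self):
        assert posterior_mode(np.array([2, 2, 3])) == 2
        assert posterior_mode(np.array([7, 7, 7])) == 7
        assert posterior_mode(np.array([1, 1, 2, 2])) == 1

    def test_hpdi_constant_draws(self):
        lo, hi = hpdi(np.full(50, 4.0))
        assert (lo, hi) == (4.0, 4.0)

    def test_hpdi_uniform_window(self):
        draws = np.arange(1, 101, dtype=float)
        lo, hi = hpdi(draws, 0.95)
        assert hi - lo == 94

    def test_hpdi_contains_mode_of_unimodal_histogram(self):
        rng = np.random.default_rng(0)
        draws = rng.poisson(30, size=5000)
        lo, hi = hpdi(draws, 0.95)
        assert lo <= posterior_mode(draws) <= hi

    def test_covariate_evidence(self):
        assert covariate_evidence(np.ones(100)) == (1.0, True)
        draws = np.concatenate([np.ones(90), -np.ones(10)])
        frac, strong = covariate_evidence(draws)
        assert frac == pytest.approx(0.9)
        assert strong
        rng = np.random.default_rng(1)
        frac, strong = covariate_evidence(rng.normal(size=4000))
        assert frac == pytest.approx(0.5, abs=0.05)
        assert not strong


def enumeration_posterior(y_obs, m_total, d_occasions):
    """Exact P(N = k) by summing over inclusion configurations, with p
    and psi integrated analytically under their uniform priors."""
    c_obs = int(y_obs.sum())
    n_obs = y_obs.shape[0]
    n_pseudo = m_total - n_obs
    post = np.zeros(m_total + 1)
    for k in range(n_pseudo + 1):
        n_incl = n_obs + k
        trials = n_incl * d_occasions
        logw = (
            np.log(comb(n_pseudo, k))
            + betaln(1 + c_obs, 1 + trials - c_obs)
            + betaln(1 + n_incl, 1 + m_total - n_incl)
        )
        post[n_incl] += np.exp(logw)
    return post / post.sum()


class TestSamplerCorrectness:
    def test_matches_enumeration_oracle(self, small_capture_dataset):
        """Gibbs posterior over N equals exhaustive enumeration on a
        tiny pool (M = 6, 2 occasions) within Monte-Carlo error."""
        aug = build_augmented_data(small_capture_dataset, 6)
        oracle = enumeration_posterior(small_capture_dataset.captures, 6, 2)
        cfg = constant_p_config(chains=2, iterations=30000, burn_in=2000,
                                thin=2, seed=3)
        post = fit_cmr(aug, cfg, diagnostics=False, saturation_tol=1.1)
        draws = post.site_draws("s")
        emp = np.bincount(draws, minlength=7) / draws.size
        assert np.abs(emp - oracle).max() < 0.01

    def test_every_draw_at_least_observed(self, small_capture_dataset):
        aug = build_augmented_data(small_capture_dataset, 20)
        cfg = constant_p_config(chains=1, iterations=2000, burn_in=200, seed=0, thin=1)
        post = fit_cmr(aug, cfg, diagnostics=False, saturation_tol=1.1)
        assert (post.site_draws("s") >= 3).all()
        assert (post.n_draws.sum(axis=2) <= 20).all()

    def test_complete_detection_degenerates_to_observed(self):
        sim = CaptureSimConfig(n_true=40, n_occasions=6, p_intercept=0.999, seed=0)
        ds, _ = simulate_capture_histories(sim)
        assert ds.n_observed == 40
        aug = build_augmented_data(ds, 120)
        cfg = constant_p_config(chains=2, iterations=3000, burn_in=500, thin=2, seed=1)
        post = fit_cmr(aug, cfg, diagnostics=False)
        draws = post.site_draws(ds.site)
        assert posterior_mode(draws) == 40
        assert np.mean(draws == 40) > 0.95

    def test_single_site_recovery(self):
        """N = 100, 10 occasions, p = 0.2: the 95% HPDI covers truth and
        the posterior mode lands within +/- 20."""
        sim = CaptureSimConfig(n_true=100, n_occasions=10, p_intercept=0.2, seed=11)
        ds, _ = simulate_capture_histories(sim)
        aug = build_augmented_data(ds, 300)
        cfg = constant_p_config(chains=3, iterations=4000, burn_in=1000, thin=2, seed=2)
        post = fit_cmr(aug, cfg, diagnostics=False)
        draws = post.site_draws(ds.site)
        lo, hi = hpdi(draws, 0.95)
        assert lo <= 100 <= hi
        assert abs(posterior_mode(draws) - 100) <= 20

    def test_saturation_raises(self):
        sim = CaptureSimConfig(n_true=60, n_occasions=8, p_intercept=0.15, seed=3)
        ds, _ = simulate_capture_histories(sim)
        from gartergen.cmr import MSaturationError

        aug = build_augmented_data(ds, ds.n_observed + 3)  # absurdly small pool
        cfg = constant_p_config(chains=1, iterations=1000, burn_in=200, thin=1, seed=0)
        with pytest.raises(MSaturationError):
            fit_cmr(aug, cfg, diagnostics=False)


class TestFullModel:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_sex_effect_recovery_and_flat_covariates(self):
        """With a strong male capture effect the posterior for beta_sex
        concentrates on the right sign while a covariate simulated with
        no effect stays centered near zero."""
        sim = CaptureSimConfig(n_true=80, n_occasions=8, p_intercept=0.25,
                               beta_sex=1.2, seed=5)
        ds, _ = simulate_capture_histories(sim)
        aug = build_augmented_data(ds, 160)
        cfg = CmrConfig(chains=2, iterations=1200, burn_in=400, thin=2, seed=3,
                        re_site=False, re_date=False, re_individual=False)
        post = fit_cmr(aug, cfg, diagnostics=True)
        frac, strong = covariate_evidence(post.scalar_draws("beta_sex"))
        assert strong and np.median(post.scalar_draws("beta_sex")) > 0
        # temperature had no simulated effect
        bt = post.scalar_draws("beta_temp")
        assert abs(np.median(bt)) < 0.5
        # abundance still recovered
        lo, hi = hpdi(post.site_draws(ds.site))
        assert lo <= 80 <= hi + 5

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_multi_site_latent_allocation(self):
        datasets = []
        for k, n in enumerate((40, 70)):
            sim = CaptureSimConfig(n_true=n, n_occasions=8, p_intercept=0.3,
                                   site=f"s{k}", seed=20 + k)
            ds, _ = simulate_capture_histories(sim)
            datasets.append(ds)
        aug = build_augmented_data(datasets, 220)
        cfg = CmrConfig(chains=2, iterations=1500, burn_in=500, thin=3, seed=4,
                        use_temperature=False, use_svl=False, use_behavior=False,
                        re_site=True, re_date=False, re_individual=False)
        post = fit_cmr(aug, cfg, diagnostics=False)
        for site, truth in zip(post.sites, (40, 70)):
            draws = post.site_draws(site)
            lo, hi = hpdi(draws)
            assert lo - 10 <= truth <= hi + 10


class TestSexRatio:
    def _posterior(self, sex_ratio, seed, n=300):
        sim = CaptureSimConfig(n_true=n, n_occasions=10, p_intercept=0.25,
                               sex_ratio=sex_ratio, seed=seed)
        ds, _ = simulate_capture_histories(sim)
        aug = build_augmented_data(ds, 2 * n)
        cfg = constant_p_config(chains=2, iterations=2500, burn_in=500, thin=2,
                                seed=seed)
        return fit_cmr(aug, cfg, diagnostics=False), ds.site

    def test_balanced_population_not_flagged(self):
        post, site = self._posterior(0.5, seed=1)
        res = sex_ratio_posterior(post, site)
        assert not res["biased"]
        lo, hi = res["hpdi"]
        assert lo <= 1.0 <= hi

    def test_male_biased_population_flagged(self):
        post, site = self._posterior(2 / 3, seed=2)  # 2:1 males
        res = sex_ratio_posterior(post, site)
        assert res["biased"]
        assert res["hpdi"][0] > 1.0


class TestHuggins:
    def test_complete_detection_returns_observed(self):
        sim = CaptureSimConfig(n_true=30, n_occasions=5, p_intercept=0.995, seed=0)
        ds, _ = simulate_capture_histories(sim)
        res = huggins_fit(ds, effects=("sex",))
        assert res["n_hat"] == pytest.approx(30, abs=0.5)

    def test_horvitz_thompson_identity(self):
        """With every history observed and high constant p the HT sum
        equals n / p*, so n_hat tracks 1/p* per individual."""
        sim = CaptureSimConfig(n_true=200, n_occasions=12, p_intercept=0.3, seed=1)
        ds, _ = simulate_capture_histories(sim)
        res = huggins_fit(ds, effects=())
        pstar_true = 1 - 0.7**12
        assert res["n_hat"] == pytest.approx(ds.n_observed / pstar_true, rel=0.05)

    def test_sex_varying_recovery(self):
        """Male/female capture probabilities 0.3/0.1, N = 200:
        conditional-likelihood abundance within 25% of truth (median
        over replicates)."""
        errs = []
        for seed in range(8):
            # females p = 0.1 (logit -2.20), males ~0.3 (logit -0.85)
            sim = CaptureSimConfig(n_true=200, n_occasions=15, p_intercept=0.1,
                                   beta_sex=1.35, seed=seed)
            ds, _ = simulate_capture_histories(sim)
            res = huggins_fit(ds)
            errs.append(res["n_hat"] / 200 - 1)
        assert abs(np.median(errs)) < 0.25

    def test_requires_recapture(self):
        ds = CaptureDataset(
            site="s",
            occasions=["2018-01-01", "2018-01-02"],
            air_temp=np.array([15.0, 15.0]),
            individuals=pd.DataFrame(
                {"individual_id": ["a"], "sex": ["F"], "svl_mm": [400.0]}
            ),
            captures=np.array([[1, 0]], dtype=np.int8),
        )
        with pytest.raises(CmrError):
            huggins_fit(ds)


class TestRegression:
    def test_collinear_points(self):
        na = {"a": 10, "b": 20, "c": 30, "d": 40}
        ratio = {k: 0.5 + 0.01 * v for k, v in na.items()}
        res = na_sexratio_regression(na, ratio)
        assert res["adj_r_squared"] == pytest.approx(1.0)
        assert res["p_value"] < 0.01

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_flat_response(self):
        na = {"a": 10, "b": 20, "c": 30, "d": 40, "e": 50}
        ratio = dict.fromkeys(na, 1.0)
        res = na_sexratio_regression(na, ratio)
        assert res["slope"] == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_r2_can_be_negative(self):
        rng = np.random.default_rng(0)
        na = {f"s{k}": float(k) for k in range(6)}
        ratio = {f"s{k}": float(rng.normal()) for k in range(6)}
        res = na_sexratio_regression(na, ratio)
        assert res["adj_r_squared"] < 1.0  # and typically negative here

    def test_exclusion_and_minimum(self):
        na = {"a": 1, "b": 2, "c": 3}
        ratio = {"a": 1.0, "b": 1.1, "c": 1.2}
        with pytest.raises(CmrError):
            na_sexratio_regression(na, ratio, exclude=["a"])


def test_read_capture_csvs_round_trip(tmp_path):
    caps = tmp_path / "caps.csv"
    occ = tmp_path / "occ.csv"
    caps.write_text(
        "individual_id,site,date,sex,svl_mm\n"
        "a,s1,2018-01-01,F,400\n"
        "a,s1,2018-01-03,F,400\n"
        "b,s1,2018-01-02,M,420\n"
    )
    occ.write_text(
        "site,date,air_temp_C\n"
        "s1,2018-01-01,14\ns1,2018-01-02,15\ns1,2018-01-03,16\n"
    )
    (ds,) = read_capture_csvs(caps, occ)
    assert ds.n_observed == 2
    assert ds.captures.tolist() == [[1, 0, 1], [0, 1, 0]]
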