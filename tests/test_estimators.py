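"""Demography and DFE estimators: recovery, nesting, summaries, MCMC."""

import numpy as np
import pytest
from sklearn.base import clone

from cnedfe.prf import (
    DemographyModel, GammaDFE, SelectionSpectrumCache,
    expected_sfs_equilibrium, expected_sfs_two_epoch,
)
from cnedfe.spectra import UnfoldedSFS
from cnedfe.estimators import (
    GammaDFEEstimator, NuisanceDFESampler, TwoEpochDemographyEstimator,
    fit_demography, lethal_fraction, nes_bin_proportions,
)

N_CHROM = 40


def make_sfs(counts, category="NONCODING", sites=10 ** 7, thr=1):
    return UnfoldedSFS(category, len(counts) + 1, counts, sites, thr)


@pytest.fixture(scope="module")
def expansion_cache():
    dem = DemographyModel(16000, omega=0.75, tau=0.45, theta=1.0)
    return SelectionSpectrumCache(dem, N_CHROM)


class TestLethalFractionAndBins:
    def test_strong_constraint_class(self):
        assert round(lethal_fraction(GammaDFE(0.18, 7.8)), 2) == 0.32

    def test_coding_class(self):
        assert round(lethal_fraction(GammaDFE(0.1, 6.25)), 2) == 0.21

    def test_zero_threshold_is_one(self):
        assert lethal_fraction(GammaDFE(0.18, 7.8), 0.0) == 1.0

    def test_bins_sum_to_one(self):
        props = nes_bin_proportions(GammaDFE(0.18, 7.8), 16000)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_lands_in_single_bin(self):
        ne = 1000.0
        mean_s = 5.0 / ne  # Ne*s = 5
        dfe = GammaDFE(5000.0, 5000.0 / mean_s)
        props = nes_bin_proportions(dfe, ne)
        assert props["1-10"] == pytest.approx(1.0, abs=1e-6)

    def test_bins_match_quadrature_of_density(self):
        from scipy import integrate as si

        dfe, ne = GammaDFE(0.19, 10.0), 16000.0
        props = nes_bin_proportions(dfe, ne)
        pdf = dfe.distribution().pdf
        val, _ = si.quad(pdf, 1.0 / ne, 10.0 / ne, limit=200)
        assert props["1-10"] == pytest.approx(val, abs=1e-8)


class TestDemographyFit:
    def test_recovery_from_simulated_expansion(self):
        truth = DemographyModel(16000, omega=0.75, tau=0.45, theta=1.0)
        unit = expected_sfs_two_epoch(0.0, truth, N_CHROM)
        theta = 20000.0
        obs = np.random.default_rng(11).poisson(theta * unit)
        est = TwoEpochDemographyEstimator(ne=16000, n_starts=6, seed=1,
                                          grid_points=250, dt=3e-3)
        est.fit(make_sfs(obs))
        assert est.omega_ == pytest.approx(0.75, rel=0.10)
        assert est.tau_ == pytest.approx(0.45, rel=0.10)
        assert est.theta_ == pytest.approx(theta, rel=0.10)

    # (omega, tau) ride a shallow likelihood ridge: recovery to 10% needs a
    # well-populated spectrum, hence the large theta above.

    def test_equilibrium_data_nests_to_equilibrium_fit(self):
        theta = 4000.0
        obs = np.random.default_rng(2).poisson(
            theta / np.arange(1, N_CHROM))
        est = TwoEpochDemographyEstimator(ne=16000, n_starts=6, seed=3,
                                          grid_points=250, dt=3e-3)
        est.fit(make_sfs(obs))
        # equilibrium log-likelihood with profiled theta
        unit = expected_sfs_equilibrium(0.0, N_CHROM, 1.0)
        th = obs.sum() / unit.sum()
        ll_eq = float(np.sum(obs * np.log(th * unit) - th * unit))
        assert est.loglik_ >= ll_eq - 0.1
        assert est.loglik_ - ll_eq < 2.0

    def test_empty_sfs_rejected(self):
        from cnedfe.elements import InputError

        with pytest.raises(InputError):
            TwoEpochDemographyEstimator().fit(
                make_sfs(np.zeros(N_CHROM - 1, dtype=int)))


class TestDFEFit:
    def test_recovery_single_replicate(self, expansion_cache):
        dfe_true = GammaDFE(0.18, 7.8)
        unit = expansion_cache.expected_sfs(dfe_true)
        obs = np.random.default_rng(21).poisson(3000.0 * unit)
        est = GammaDFEEstimator(cache=expansion_cache, n_starts=8, seed=5)
        est.fit(make_sfs(obs, "NVR"))
        assert est.shape_ci_[0] <= 0.18 <= est.shape_ci_[1]
        assert est.shape_ == pytest.approx(0.18, rel=0.5)

    def test_neutral_data_not_significant_vs_neutral_model(self, expansion_cache):
        """LRT of gamma DFE vs neutral on neutral data: not significant."""
        dem = expansion_cache.demography
        unit = expected_sfs_two_epoch(0.0,
                                      DemographyModel(dem.ne, dem.omega,
                                                      dem.tau, 1.0), N_CHROM)
        obs = np.random.default_rng(33).poisson(2000.0 * unit)
        est = GammaDFEEstimator(cache=expansion_cache, n_starts=8, seed=6)
        est.fit(make_sfs(obs, "NVR"))
        th = obs.sum() / unit.sum()
        ll_neutral = float(np.sum(obs * np.log(th * unit) - th * unit))
        lrt = 2.0 * (est.loglik_ - ll_neutral)
        from scipy import stats
        # 2 extra parameters; mixture null makes this conservative
        assert stats.chi2.sf(max(lrt, 0.0), df=2) > 0.05

    def test_thresholded_sfs_uses_only_common_classes(self, expansion_cache):
        dfe_true = GammaDFE(0.18, 7.8)
        unit = expansion_cache.expected_sfs(dfe_true)
        obs = np.random.default_rng(8).poisson(4000.0 * unit)
        full = make_sfs(obs.copy(), "NVR")
        masked = full.thresholded(6)
        est = GammaDFEEstimator(cache=expansion_cache, n_starts=6, seed=7)
        est.fit(masked)
        # classes below the threshold never enter: zeroing them changes nothing
        obs2 = obs.copy()
        obs2[:5] = 0
        est2 = GammaDFEEstimator(cache=expansion_cache, n_starts=6, seed=7)
        est2.fit(make_sfs(obs2, "NVR", thr=6))
        assert est.shape_ == pytest.approx(est2.shape_, rel=1e-9)

    def test_sklearn_protocol(self):
        est = GammaDFEEstimator(ne=1000.0, n_starts=2, seed=1)
        params = est.get_params()
        assert params["ne"] == 1000.0
        cloned = clone(est)
        assert cloned.get_params()["seed"] == 1
        cloned.set_params(seed=9)
        assert cloned.seed == 9


class TestNuisanceSampler:
    @pytest.fixture(scope="class")
    def fitted(self):
        """Simulated neutral + selected spectra with all r_i = 1."""
        rng = np.random.default_rng(17)
        n = 30
        dacs = np.arange(1, n)
        neutral_exp = 4000.0 / dacs
        shape_true, mean_true = 0.2, 300.0  # scaled effect S = 4 Ne s
        from scipy import stats as ss
        s_grid = np.exp(np.linspace(np.log(1e-3), np.log(64000.0), 200))
        spectra = np.array([expected_sfs_equilibrium(-S, n, 1.0)
                            for S in s_grid])
        dist = ss.gamma(a=shape_true, scale=mean_true / shape_true)
        dens = dist.pdf(s_grid) * s_grid
        sel_unit = np.trapezoid(dens[:, None] * spectra, np.log(s_grid), axis=0)
        sel_unit += dist.cdf(s_grid[0]) / dacs  # below-grid mass ~ neutral
        sel_exp = 3000.0 * (sel_unit / sel_unit[0])
        obs_neu = rng.poisson(neutral_exp)
        obs_sel = rng.poisson(sel_exp)
        sampler = NuisanceDFESampler(ne=16000, n_iter=12000, n_chains=2,
                                     seed=42, rhat_threshold=1.1)
        sampler.fit(make_sfs(obs_sel, "NVR"), make_sfs(obs_neu))
        return sampler, shape_true, mean_true

    def test_posterior_covers_truth(self, fitted):
        sampler, shape_true, mean_true = fitted
        assert sampler.shape_ci_[0] <= shape_true <= sampler.shape_ci_[1]
        assert sampler.mean_scaled_ci_[0] <= mean_true <= sampler.mean_scaled_ci_[1]

    def test_bin_proportions_sum_to_one(self, fitted):
        sampler, _, _ = fitted
        assert sum(sampler.nes_bins_.values()) == pytest.approx(1.0, abs=1e-6)

    def test_rhat_reported(self, fitted):
        sampler, _, _ = fitted
        assert sampler.rhat_shape_ < 1.1 and sampler.rhat_mean_ < 1.1

    def test_neutral_selected_class_gives_small_mean_effect(self):
        rng = np.random.default_rng(3)
        n = 30
        dacs = np.arange(1, n)
        obs_neu = rng.poisson(4000.0 / dacs)
        obs_sel = rng.poisson(2500.0 / dacs)
        sampler = NuisanceDFESampler(ne=16000, n_iter=6000, n_chains=2,
                                     seed=11, strict_convergence=False)
        sampler.fit(make_sfs(obs_sel, "NVR"), make_sfs(obs_neu))
        # posterior concentrates at weak selection: most mass effectively neutral
        assert sampler.nes_bins_["<1"] + sampler.nes_bins_["1-10"] > 0.5

    def test_mismatched_sample_sizes_rejected(self):
        from cnedfe.elements import InputError

        with pytest.raises(InputError):
            NuisanceDFESampler().fit(
                make_sfs(np.ones(9, dtype=int), "NVR"),
                make_sfs(np.ones(19, dtype=int)))


def test_fit_demography_wrapper_returns_model():
    obs = np.random.default_rng(1).poisson(3000.0 / np.arange(1, 20))
    model = fit_demography(make_sfs(obs), ne=12000, n_starts=3, seed=2,
                           grid_points=200, dt=5e-3)
    assert isinstance(model, DemographyModel)
    assert model.theta > 0
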