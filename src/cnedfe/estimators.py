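"""Maximum-likelihood and Bayesian estimators for demography and the DFE.

The fitting strategy is two-step: the demographic parameters (omega, tau,
theta) of a two-epoch history are first fitted by Poisson maximum likelihood
on a putatively neutral site class; the gamma distribution of fitness
effects (shape, rate, theta) is then fitted on a selected class with the
demography held fixed. An alternative estimator replaces the explicit
demography with per-frequency-class nuisance multipliers shared between the
neutral and selected spectra, with the posterior explored by MCMC
(Metropolis-within-Gibbs) and summarized by medians and central 95%
credibility intervals.

All estimators follow the scikit-learn protocol (``get_params`` /
``set_params``, ``fit``, fitted attributes with a trailing underscore) and
can be cloned and composed accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .elements import InputError
from .prf import (
    DemographyModel,
    GammaDFE,
    SelectionSpectrumCache,
    expected_sfs_equilibrium,
    expected_sfs_two_epoch,
)
from .spectra import UnfoldedSFS

__all__ = [
    "TwoEpochDemographyEstimator", "GammaDFEEstimator", "NuisanceDFESampler",
    "fit_demography", "fit_dfe", "fit_dfe_nuisance_mcmc",
    "lethal_fraction", "nes_bin_proportions", "NES_BIN_EDGES",
]

#: Ne*s bin edges used to summarize the DFE (upper-open last bin).
NES_BIN_EDGES = (1.0, 10.0, 100.0, 1000.0, 10000.0)
NES_BIN_LABELS = ("<1", "1-10", "10-100", "100-1000", "1000-10000", ">10000")


def lethal_fraction(dfe: GammaDFE, threshold_s: float = 0.01) -> float:
    """P(s > threshold): the proportion of mutations with selection
    coefficient magnitude beyond the threshold (default |s| > 1%)."""
    if threshold_s < 0:
        raise InputError("threshold must be >= 0")
    return float(dfe.distribution().sf(threshold_s))


def nes_bin_proportions(
    dfe: GammaDFE, ne: float, edges: tuple[float, ...] = NES_BIN_EDGES
) -> dict[str, float]:
    """Probability mass of the DFE in Ne*s bins (sums to 1)."""
    if ne <= 0:
        raise InputError("Ne must be positive")
    dist = dfe.distribution()
    cuts = [e / ne for e in edges]
    cdf = np.array([0.0] + [dist.cdf(c) for c in cuts] + [1.0])
    mass = np.diff(cdf)
    labels = [f"<{edges[0]:g}"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f">{edges[-1]:g}"]
    return dict(zip(labels, mass.tolist()))


def _counts_and_mask(sfs: UnfoldedSFS) -> tuple[np.ndarray, np.ndarray]:
    """Observed counts and the boolean mask of DAC classes entering the
    likelihood (classes below the SFS's DAC threshold are excluded)."""
    counts = np.asarray(sfs.counts, dtype=float)
    mask = np.arange(1, sfs.n_chromosomes) >= sfs.dac_threshold
    return counts, mask


def _poisson_loglik(obs: np.ndarray, exp: np.ndarray) -> float:
    exp = np.maximum(exp, 1e-300)
    return float(np.sum(obs * np.log(exp) - exp))


def _profiled_theta(obs: np.ndarray, unit: np.ndarray) -> float:
    """MLE of theta given unit-theta expectations (Poisson likelihood)."""
    denom = unit.sum()
    return float(obs.sum() / denom) if denom > 0 else 0.0


class TwoEpochDemographyEstimator(BaseEstimator):
    """Poisson-ML fit of (omega, tau, theta) on a neutral unfolded SFS.

    Parameters
    ----------
    ne : reference (current) effective population size recorded on the model;
        it does not enter the neutral likelihood but anchors later scaling.
    n_starts : multi-start count for the bounded quasi-Newton optimizer.
    seed : seed of the start-point generator.
    omega_bounds, tau_bounds : box constraints on the search.
    grid_points, dt : diffusion-solver resolution.

    Attributes (after fit)
    ----------------------
    omega_, tau_, theta_ : fitted parameters.
    loglik_ : maximized Poisson log-likelihood (up to data-only terms).
    model_ : the fitted :class:`DemographyModel`.
    """

    def __init__(
        self,
        ne: float = 16000,
        n_starts: int = 25,
        seed: int = 20140725,
        omega_bounds: tuple[float, float] = (0.05, 20.0),
        tau_bounds: tuple[float, float] = (1e-3, 10.0),
        grid_points: int = 300,
        dt: float = 2e-3,
    ) -> None:
        self.ne = ne
        self.n_starts = n_starts
        self.seed = seed
        self.omega_bounds = omega_bounds
        self.tau_bounds = tau_bounds
        self.grid_points = grid_points
        self.dt = dt

    def _unit_sfs(self, omega: float, tau: float, n: int) -> np.ndarray:
        model = DemographyModel(self.ne, omega, tau, theta=1.0)
        return expected_sfs_two_epoch(0.0, model, n,
                                      grid_points=self.grid_points, dt=self.dt)

    def fit(self, X: UnfoldedSFS, y: None = None) -> "TwoEpochDemographyEstimator":
        if X.n_snps == 0:
            raise InputError("neutral SFS has no variants")
        obs, mask = _counts_and_mask(X)
        n = X.n_chromosomes
        rng = np.random.default_rng(self.seed)
        lob = np.log(self.omega_bounds)
        ltb = np.log(self.tau_bounds)

        def negloglik(params: np.ndarray) -> float:
            omega, tau = np.exp(params)
            try:
                unit = self._unit_sfs(omega, tau, n)[mask]
            except FloatingPointError:
                return 1e12
            theta = _profiled_theta(obs[mask], unit)
            return -_poisson_loglik(obs[mask], theta * unit)

        best = None
        starts = [np.array([np.log(1.0), np.log(0.5)])] + [
            rng.uniform([lob[0], ltb[0]], [lob[1], ltb[1]])
            for _ in range(self.n_starts - 1)
        ]
        for x0 in starts:
            res = optimize.minimize(
                negloglik, x0, method="L-BFGS-B",
                bounds=[tuple(lob), tuple(ltb)],
            )
            if best is None or res.fun < best.fun:
                best = res
        omega, tau = np.exp(best.x)
        unit = self._unit_sfs(omega, tau, n)[mask]
        theta = _profiled_theta(obs[mask], unit)
        self.omega_ = float(omega)
        self.tau_ = float(tau)
        self.theta_ = theta
        self.loglik_ = -float(best.fun)
        self.model_ = DemographyModel(self.ne, self.omega_, self.tau_, self.theta_)
        self.flat_likelihood_ = bool(not best.success and best.nit <= 1)
        self._n_chromosomes = X.n_chromosomes
        return self

    def expected_sfs_(self) -> np.ndarray:
        """Fitted expected SFS at the data's sample size."""
        return self.theta_ * self._unit_sfs(self.omega_, self.tau_,
                                            self._n_chromosomes)


class GammaDFEEstimator(BaseEstimator):
    """Poisson-ML fit of a gamma DFE (shape, rate, theta) on a selected SFS,
    with the demography held fixed.

    A per-s spectrum cache is built once per fit (or supplied via
    ``cache``), so repeated likelihood evaluations are cheap.

    Attributes (after fit)
    ----------------------
    shape_, rate_, theta_ : fitted parameters; dfe_ the :class:`GammaDFE`.
    loglik_ : maximized log-likelihood.
    shape_ci_ : profile-likelihood ~95% interval for the shape.
    boundary_convergence_ : True when the optimum sits on a box boundary.
    """

    def __init__(
        self,
        demography: DemographyModel | None = None,
        ne: float | None = None,
        scaling: float = 4.0,
        n_starts: int = 25,
        seed: int = 20140725,
        shape_bounds: tuple[float, float] = (0.01, 10.0),
        rate_bounds: tuple[float, float] = (1e-3, 1e4),
        cache: SelectionSpectrumCache | None = None,
        cache_grid: int = 160,
        grid_points: int = 300,
        dt: float = 2e-3,
        profile_points: int = 25,
    ) -> None:
        self.demography = demography
        self.ne = ne
        self.scaling = scaling
        self.n_starts = n_starts
        self.seed = seed
        self.shape_bounds = shape_bounds
        self.rate_bounds = rate_bounds
        self.cache = cache
        self.cache_grid = cache_grid
        self.grid_points = grid_points
        self.dt = dt
        self.profile_points = profile_points

    def _get_cache(self, n: int) -> SelectionSpectrumCache:
        if self.cache is not None:
            if self.cache.n != n:
                raise InputError("cache sample size != SFS sample size")
            return self.cache
        demography = self.demography or DemographyModel(self.ne or 10000.0)
        return SelectionSpectrumCache(
            demography, n, self.ne, scaling=self.scaling,
            n_grid=self.cache_grid, grid_points=self.grid_points, dt=self.dt,
        )

    def fit(self, X: UnfoldedSFS, y: None = None) -> "GammaDFEEstimator":
        if X.n_snps == 0:
            raise InputError("selected SFS has no variants")
        obs, mask = _counts_and_mask(X)
        cache = self._get_cache(X.n_chromosomes)
        self.cache_ = cache
        lsb = np.log(self.shape_bounds)
        lrb = np.log(self.rate_bounds)

        def negloglik(params: np.ndarray) -> float:
            shape, rate = np.exp(params)
            unit = cache.expected_sfs(GammaDFE(shape, rate))[mask]
            theta = _profiled_theta(obs[mask], unit)
            return -_poisson_loglik(obs[mask], theta * unit)

        rng = np.random.default_rng(self.seed)
        starts = [np.log([0.2, 10.0])] + [
            rng.uniform([lsb[0], lrb[0]], [lsb[1], lrb[1]])
            for _ in range(self.n_starts - 1)
        ]
        best = None
        for x0 in starts:
            res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                    bounds=[tuple(lsb), tuple(lrb)])
            if best is None or res.fun < best.fun:
                best = res
        shape, rate = np.exp(best.x)
        unit = cache.expected_sfs(GammaDFE(shape, rate))[mask]
        self.shape_ = float(shape)
        self.rate_ = float(rate)
        self.theta_ = _profiled_theta(obs[mask], unit)
        self.loglik_ = -float(best.fun)
        self.dfe_ = GammaDFE(self.shape_, self.rate_)
        tol = 1e-3
        self.boundary_convergence_ = bool(
            min(abs(best.x[0] - lsb[0]), abs(best.x[0] - lsb[1])) < tol
            or min(abs(best.x[1] - lrb[0]), abs(best.x[1] - lrb[1])) < tol
        )
        self.shape_ci_ = self._profile_shape_ci(obs, mask, cache)
        return self

    def _profile_shape_ci(
        self, obs: np.ndarray, mask: np.ndarray, cache: SelectionSpectrumCache
    ) -> tuple[float, float]:
        """Profile-likelihood ~95% interval: shapes whose profiled (over rate
        and theta) log-likelihood is within chi2(1)/2 = 1.92 of the maximum;
        boundaries located by bisection on the profile."""
        lrb = np.log(self.rate_bounds)

        def profile_ll(shape: float) -> float:
            def nll(lr: float) -> float:
                unit = cache.expected_sfs(GammaDFE(shape, float(np.exp(lr))))[mask]
                theta = _profiled_theta(obs[mask], unit)
                return -_poisson_loglik(obs[mask], theta * unit)

            res = optimize.minimize_scalar(nll, bounds=tuple(lrb),
                                           method="bounded")
            return -res.fun

        cutoff = self.loglik_ - stats.chi2.ppf(0.95, df=1) / 2.0

        def crossing(direction: int) -> float:
            """Walk outward from the MLE until the profile drops below the
            cutoff, then bisect; returns the box bound if never crossed."""
            bound = self.shape_bounds[1] if direction > 0 else self.shape_bounds[0]
            log_mle = np.log(self.shape_)
            step = 0.15 * direction
            prev = log_mle
            for k in range(1, 40):
                cur = log_mle + k * step
                if direction > 0 and cur >= np.log(bound):
                    cur = np.log(bound)
                if direction < 0 and cur <= np.log(bound):
                    cur = np.log(bound)
                if profile_ll(float(np.exp(cur))) < cutoff:
                    root = optimize.brentq(
                        lambda ls: profile_ll(float(np.exp(ls))) - cutoff,
                        min(prev, cur), max(prev, cur), xtol=1e-3,
                    )
                    return float(np.exp(root))
                prev = cur
                if cur == np.log(bound):
                    return float(bound)
            return float(bound)

        return (crossing(-1), crossing(+1))

    def expected_sfs_(self, X: UnfoldedSFS | None = None) -> np.ndarray:
        return self.cache_.expected_sfs(self.dfe_, self.theta_)


class NuisanceDFESampler(BaseEstimator):
    """Bayesian DFE fit with shared per-frequency-class nuisance multipliers.

    Each DAC class i carries a multiplier r_i applied to both the neutral
    (theta_n / i) and selected (theta_s * m_i(shape, mean)) expected counts,
    absorbing demography and other class-specific distortions; r_1 = 1 for
    identifiability. The selected-class expectation integrates equilibrium
    per-S spectra over a gamma distribution of the scaled effect
    S = scaling * Ne * s with parameters (shape, mean).

    The multipliers are marginalized analytically: with a Gamma(a0, a0)
    prior on each r_i (mean 1), the joint Poisson likelihood of the neutral
    and selected counts in class i integrates to a closed negative-binomial
    form, leaving only (theta_n, theta_s, shape, mean) to sample. These four
    use component-wise random-walk Metropolis on the log scale; collapsing
    the multipliers removes the strong Gibbs coupling that otherwise makes
    the chain mix extremely slowly. Convergence is monitored with the
    split-chain potential scale reduction factor on shape and mean.

    Attributes (after fit)
    ----------------------
    shape_, shape_ci_ : posterior median and central 95% interval.
    mean_scaled_, mean_scaled_ci_ : same for the mean scaled effect.
    nes_bins_ : posterior-mean Ne*s bin proportions.
    rhat_shape_, rhat_mean_ : split-chain diagnostics.
    """

    def __init__(
        self,
        ne: float = 16000,
        scaling: float = 4.0,
        n_iter: int = 50000,
        n_chains: int = 4,
        burn_fraction: float = 0.5,
        seed: int = 20140725,
        proposal_sd: float = 0.25,
        proposal_sd_mean: float = 0.8,
        proposal_sd_theta: float = 0.05,
        prior_r_concentration: float = 2.0,
        rhat_threshold: float = 1.05,
        s_grid: int = 160,
        s_max: float = 1.0,
        strict_convergence: bool = True,
    ) -> None:
        self.ne = ne
        self.scaling = scaling
        self.n_iter = n_iter
        self.n_chains = n_chains
        self.burn_fraction = burn_fraction
        self.seed = seed
        self.proposal_sd = proposal_sd
        self.proposal_sd_mean = proposal_sd_mean
        self.proposal_sd_theta = proposal_sd_theta
        self.prior_r_concentration = prior_r_concentration
        self.rhat_threshold = rhat_threshold
        self.s_grid = s_grid
        self.s_max = s_max
        self.strict_convergence = strict_convergence

    # -- model pieces -------------------------------------------------------

    def _build_cache(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Equilibrium unit spectra on a log grid of scaled effects S."""
        s_scaled = np.exp(np.linspace(np.log(1e-4), np.log(self.scaling * self.ne * self.s_max),
                                      self.s_grid))
        spectra = np.array([expected_sfs_equilibrium(-float(S), n, 1.0)
                            for S in s_scaled])
        return s_scaled, spectra

    def _selected_unit(self, shape: float, mean: float,
                       s_scaled: np.ndarray, spectra: np.ndarray,
                       neutral: np.ndarray) -> np.ndarray:
        dist = stats.gamma(a=shape, scale=mean / shape)
        dens = dist.pdf(s_scaled) * s_scaled
        out = np.trapezoid(dens[:, None] * spectra, np.log(s_scaled), axis=0)
        return out + dist.cdf(s_scaled[0]) * neutral

    # -- sampler ------------------------------------------------------------

    def fit(
        self, X: UnfoldedSFS, y: UnfoldedSFS
    ) -> "NuisanceDFESampler":
        """Fit on a selected spectrum ``X`` with neutral reference ``y``."""
        sel, neu = X, y
        if sel.n_chromosomes != neu.n_chromosomes:
            raise InputError("selected and neutral spectra must share n")
        n = sel.n_chromosomes
        obs_sel, mask_s = _counts_and_mask(sel)
        obs_neu, mask_n = _counts_and_mask(neu)
        mask = mask_s & mask_n
        idx = np.where(mask)[0]
        dac = idx + 1.0
        xs = obs_sel[idx]
        xn = obs_neu[idx]
        s_scaled, spectra_full = self._build_cache(n)
        spectra = spectra_full[:, idx]
        self._log_s = np.log(s_scaled)
        neutral_unit = (1.0 / dac)

        n_keep = int(self.n_iter * (1 - self.burn_fraction))
        chains_shape = np.empty((self.n_chains, n_keep))
        chains_mean = np.empty((self.n_chains, n_keep))
        bins_acc = np.zeros(len(NES_BIN_LABELS))
        bins_count = 0
        a0 = self.prior_r_concentration

        def collapsed_loglik(theta_n: float, theta_s: float,
                             sel_unit: np.ndarray) -> float:
            """Joint log-likelihood of both spectra with the r_i integrated
            out against Gamma(a0, a0); r of the first retained class is 1."""
            a = theta_n * neutral_unit
            b = np.maximum(theta_s * sel_unit, 1e-300)
            # first class: plain Poisson at r = 1
            ll = (xn[0] * np.log(a[0]) - a[0]
                  + xs[0] * np.log(b[0]) - b[0])
            xa, xb = xn[1:], xs[1:]
            aa, bb = a[1:], b[1:]
            total = xa + xb
            ll += float(np.sum(
                xa * np.log(aa) + xb * np.log(bb)
                + special.gammaln(a0 + total) - special.gammaln(a0)
                + a0 * np.log(a0) - (a0 + total) * np.log(a0 + aa + bb)
            ))
            return ll

        # update schedule: the weakly identified (shape, mean) directions get
        # more frequent moves than the well-identified thetas
        schedule = (0, 2, 3, 1, 2, 3)
        sds = (self.proposal_sd_theta, self.proposal_sd_theta,
               self.proposal_sd, self.proposal_sd_mean)

        for c in range(self.n_chains):
            rng = np.random.default_rng(self.seed + 1000 * c)
            # state: log(theta_n), log(theta_s), log(shape), log(mean S)
            state = np.array([
                np.log(max(xn.sum() / np.sum(neutral_unit), 1.0)),
                np.log(max(xs.sum(), 1.0)),
                np.log(0.2) + 0.5 * rng.normal(),
                np.log(100.0) + 1.0 * rng.normal(),
            ])
            sel_unit = self._sel_unit_cached(state[2], state[3], s_scaled,
                                             spectra, neutral_unit)
            cur_ll = collapsed_loglik(np.exp(state[0]), np.exp(state[1]),
                                      sel_unit)
            kept = 0
            for it in range(self.n_iter):
                j = schedule[it % len(schedule)]
                prop = state.copy()
                if j == 3 and rng.uniform() < 0.25:
                    # long-range jump across the flat ridge in the mean
                    # (uniform independence proposal on the log-mean range)
                    prop[3] = rng.uniform(np.log(1e-1), np.log(1e7))
                else:
                    prop[j] += sds[j] * rng.normal()
                if j >= 2:
                    prop_unit = self._sel_unit_cached(prop[2], prop[3],
                                                      s_scaled, spectra,
                                                      neutral_unit)
                    # compensate theta_s so the total expected count is
                    # unchanged (log-space shear, unit Jacobian): DFE moves
                    # then compete on spectrum shape, not on overall scale
                    prop[1] += np.log(sel_unit.sum()) - np.log(prop_unit.sum())
                else:
                    prop_unit = sel_unit
                if (np.log(1e-3) <= prop[2] <= np.log(50.0)
                        and np.log(1e-3) <= prop[3] <= np.log(1e7)):
                    prop_ll = collapsed_loglik(np.exp(prop[0]),
                                               np.exp(prop[1]), prop_unit)
                    if np.log(rng.uniform()) < prop_ll - cur_ll:
                        state, sel_unit, cur_ll = prop, prop_unit, prop_ll
                if it >= self.n_iter - n_keep:
                    chains_shape[c, kept] = np.exp(state[2])
                    chains_mean[c, kept] = np.exp(state[3])
                    if kept % 50 == 0:
                        dfe = GammaDFE(
                            np.exp(state[2]),
                            np.exp(state[2])
                            / (np.exp(state[3]) / (self.scaling * self.ne)))
                        props = nes_bin_proportions(dfe, self.ne)
                        bins_acc += np.array([props[k] for k in props])
                        bins_count += 1
                    kept += 1

        # diagnostics on the log scale (both are scale-like parameters with
        # heavy-tailed posteriors; raw-scale variances are tail-dominated)
        self.rhat_shape_ = _split_rhat(np.log(chains_shape))
        self.rhat_mean_ = _split_rhat(np.log(chains_mean))
        if self.strict_convergence and max(self.rhat_shape_, self.rhat_mean_) > self.rhat_threshold:
            self.trace_shape_ = chains_shape
            self.trace_mean_ = chains_mean
            raise RuntimeError(
                f"MCMC not converged: rhat shape={self.rhat_shape_:.3f}, "
                f"mean={self.rhat_mean_:.3f} (traces on .trace_shape_/.trace_mean_)"
            )
        flat_shape = chains_shape.ravel()
        flat_mean = chains_mean.ravel()
        self.shape_ = float(np.median(flat_shape))
        self.shape_ci_ = tuple(np.percentile(flat_shape, [2.5, 97.5]).tolist())
        self.mean_scaled_ = float(np.median(flat_mean))
        self.mean_scaled_ci_ = tuple(np.percentile(flat_mean, [2.5, 97.5]).tolist())
        self.nes_bins_ = dict(zip(NES_BIN_LABELS, (bins_acc / max(bins_count, 1)).tolist()))
        mean_s = self.mean_scaled_ / (self.scaling * self.ne)
        self.dfe_ = GammaDFE(self.shape_, self.shape_ / mean_s)
        return self

    def _sel_unit_cached(self, log_shape, log_mean, s_scaled, spectra, neutral_unit):
        shape = float(np.exp(np.clip(log_shape, np.log(1e-3), np.log(50.0))))
        mean = float(np.exp(np.clip(log_mean, np.log(1e-3), np.log(1e7))))
        scale = mean / shape
        # direct gamma pdf/cdf (hot path: avoid scipy frozen-distribution overhead)
        log_dens = ((shape - 1.0) * np.log(s_scaled) - s_scaled / scale
                    - special.gammaln(shape) - shape * np.log(scale))
        dens = np.exp(log_dens) * s_scaled
        out = np.trapezoid(dens[:, None] * spectra, self._log_s, axis=0)
        low_mass = special.gammainc(shape, s_scaled[0] / scale)
        return out + low_mass * neutral_unit

    @staticmethod
    def _sel_loglik(xs, theta_s, r, sel_unit):
        exp = np.maximum(theta_s * r * sel_unit, 1e-300)
        return float(np.sum(xs * np.log(exp) - exp))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin)."""
    m, length = chains.shape
    half = length // 2
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w)) if w > 0 else np.inf


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_demography(neutral_sfs: UnfoldedSFS, **kwargs) -> DemographyModel:
    """Fit the two-epoch demography on a neutral SFS (Poisson ML)."""
    est = TwoEpochDemographyEstimator(**kwargs).fit(neutral_sfs)
    return est.model_


def fit_dfe(
    selected_sfs: UnfoldedSFS,
    fixed_demography: DemographyModel,
    **kwargs,
) -> GammaDFEEstimator:
    """Fit a gamma DFE on a selected SFS with the demography fixed."""
    return GammaDFEEstimator(demography=fixed_demography, **kwargs).fit(selected_sfs)


def fit_dfe_nuisance_mcmc(
    selected_sfs: UnfoldedSFS,
    neutral_sfs: UnfoldedSFS,
    **kwargs,
) -> NuisanceDFESampler:
    """Nuisance-multiplier Bayesian DFE fit (posterior medians + 95% CIs)."""
    return NuisanceDFESampler(**kwargs).fit(selected_sfs, neutral_sfs)
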