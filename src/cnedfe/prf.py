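"""Poisson-Random-Field machinery for unfolded site-frequency spectra.

Under the PRF model the number of segregating sites observed at derived
allele count i (out of n sampled chromosomes) is Poisson with mean

    E[xi_i] = theta * Integral_0^1 C(n,i) x^i (1-x)^(n-i) H(x) dx,

where H is the population-scale density of derived-allele frequencies. At
mutation-drift-selection equilibrium with population-scaled selection
coefficient gamma (= 4*Ne*s; negative for deleterious derived alleles),

    H(x; gamma) = (1 - exp(-gamma (1-x))) / [x (1-x) (1 - exp(-gamma))],

with the neutral limit H = 1/x and hence E[xi_i] = theta / i.

Away from equilibrium (a single instantaneous population-size change of
ratio ``omega`` = ancestral/current at scaled time ``tau`` before present)
the frequency density is obtained by integrating the 1-D Wright-Fisher
forward diffusion with an implicit finite-difference scheme on a nonuniform
frequency grid, starting from the discrete stationary density of the
ancestral epoch. Time is measured in units of 2*Ne(current) generations and
the relative size enters the diffusion term as nu(t) = N(t)/Ne.

A gamma distribution of (deleterious) fitness effects s is integrated over
either by adaptive Gauss-Legendre quadrature in log s (node-doubling
convergence check) or, for repeated likelihood evaluations, through a cached
grid of per-s spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, special, stats
from scipy.linalg import solve_banded

from .elements import InputError

__all__ = [
    "GammaDFE", "DemographyModel", "sojourn_density",
    "expected_sfs_equilibrium", "expected_sfs_two_epoch",
    "integrate_gamma_dfe", "SelectionSpectrumCache",
]

#: |gamma| above which the two-epoch solution is replaced by the equilibrium
#: closed form: strongly selected alleles reach mutation-selection balance on
#: a time scale ~1/|gamma|, much faster than the demographic time scale.
STRONG_SELECTION_GAMMA = 500.0


@dataclass
class GammaDFE:
    """Gamma distribution of deleterious selection coefficients.

    ``shape`` and ``rate`` parameterize the magnitude of the (deleterious)
    raw selection coefficient s >= 0; mean effect = shape / rate. The
    population-scaled coefficient entering the PRF is ``-scaling * Ne * s``
    (scaling 4 by default).
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise InputError("gamma DFE shape and rate must be positive")

    @property
    def mean_s(self) -> float:
        return self.shape / self.rate

    def mean_scaled(self, ne: float, scaling: float = 4.0) -> float:
        return scaling * ne * self.mean_s

    def distribution(self) -> stats.rv_continuous:
        return stats.gamma(a=self.shape, scale=1.0 / self.rate)


@dataclass
class DemographyModel:
    """Single-population two-epoch history.

    ``omega`` is the ratio of ancestral to current size; ``tau`` the time
    since the size change in units of 2*Ne (current) generations. omega = 1
    or tau -> infinity reduce to equilibrium at the current size. ``theta``
    is the per-class mutation parameter 4*Ne*mu*L.
    """

    ne: float
    omega: float = 1.0
    tau: float = 0.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise InputError("omega must be positive")
        if self.tau < 0:
            raise InputError("tau must be >= 0")

    @property
    def is_equilibrium(self) -> bool:
        return self.omega == 1.0


# ---------------------------------------------------------------------------
# Equilibrium closed form
# ---------------------------------------------------------------------------

def _sojourn_ratio(gamma: float, x: np.ndarray) -> np.ndarray:
    """(1 - e^{-gamma(1-x)}) / (1 - e^{-gamma}), stable for large |gamma|."""
    x = np.asarray(x, dtype=float)
    if gamma == 0.0:
        return 1.0 - x
    if gamma < 0:
        g = -gamma
        # rewrite with positive exponents kept <= 0
        return np.exp(-g * x) * np.expm1(-g * (1.0 - x)) / np.expm1(-g)
    return np.expm1(-gamma * (1.0 - x)) / np.expm1(-gamma)


def sojourn_density(x: np.ndarray, gamma: float) -> np.ndarray:
    """Equilibrium frequency density H(x; gamma) per unit theta."""
    x = np.asarray(x, dtype=float)
    return _sojourn_ratio(gamma, x) / (x * (1.0 - x))


@lru_cache(maxsize=64)
def _log_binom(n: int) -> np.ndarray:
    i = np.arange(1, n)
    return (special.gammaln(n + 1) - special.gammaln(i + 1)
            - special.gammaln(n - i + 1))


def expected_sfs_equilibrium(
    gamma: float, n: int, theta: float = 1.0
) -> np.ndarray:
    """Expected unfolded SFS at DAC 1..n-1 at equilibrium.

    Neutral (gamma = 0) uses the closed form theta/i; otherwise each entry is
    an adaptive-quadrature integral of the binomial-sampled sojourn density.
    """
    if n < 2:
        raise InputError("n must be >= 2")
    if gamma == 0.0:
        return theta / np.arange(1, n, dtype=float)
    lb = _log_binom(n)
    out = np.empty(n - 1)
    for idx, i in enumerate(range(1, n)):
        c = np.exp(lb[idx])

        def f(x: float, i: int = i, c: float = c) -> float:
            return c * x ** (i - 1) * (1 - x) ** (n - i - 1) * _sojourn_ratio(gamma, x)

        if gamma < -50.0:
            # deleterious mass concentrates at x <~ 1/|gamma|: split the range
            cut = min(1.0, 50.0 / abs(gamma))
            val, _ = integrate.quad(f, 0.0, cut, limit=200)
            tail, _ = integrate.quad(f, cut, 1.0, limit=200)
            val += tail
        else:
            pts = [min(1.0 / abs(gamma), 0.5)] if abs(gamma) > 10 else None
            val, _ = integrate.quad(f, 0.0, 1.0, limit=200, points=pts)
        out[idx] = theta * val
    return out


# ---------------------------------------------------------------------------
# Two-epoch diffusion solver
# ---------------------------------------------------------------------------

def frequency_grid(npts: int = 400, crowding: float = 8.0) -> np.ndarray:
    """Nonuniform grid on [0, 1], refined near both boundaries."""
    u = np.linspace(0.0, 1.0, npts)
    x = 1.0 / (1.0 + np.exp(crowding * (0.5 - u)))
    return (x - x[0]) / (x[-1] - x[0])


def _operator(xx: np.ndarray, gamma: float, nu: float):
    """Tridiagonal finite-volume generator L with flux
    F = M phi - (1/2) d/dx(V phi), M = (gamma/2) x(1-x), V = x(1-x)/nu."""
    n = len(xx)
    dx = np.diff(xx)
    xm = 0.5 * (xx[:-1] + xx[1:])
    m_half = 0.5 * gamma * xm * (1.0 - xm)
    v = xx * (1.0 - xx) / nu
    w = np.empty(n)
    w[0] = dx[0] / 2
    w[-1] = dx[-1] / 2
    w[1:-1] = 0.5 * (dx[:-1] + dx[1:])
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    a_l = 0.5 * m_half + v[:-1] / (2.0 * dx)      # coefficient of phi_j in F_j
    a_r = 0.5 * m_half - v[1:] / (2.0 * dx)       # coefficient of phi_{j+1} in F_j
    np.add.at(diag, np.arange(n - 1), -a_l / w[:-1])
    np.add.at(upper, np.arange(n - 1), -a_r / w[:-1])
    np.add.at(lower, np.arange(1, n), a_l / w[1:])
    np.add.at(diag, np.arange(1, n), a_r / w[1:])
    return lower, diag, upper, w


def _injection(xx: np.ndarray, theta: float) -> np.ndarray:
    """Mutational influx: new derived alleles enter at the lowest interior
    frequency such that the neutral equilibrium density is theta/x."""
    inj = np.zeros(len(xx))
    inj[1] = theta / 2.0 / xx[1] * 2.0 / (xx[2] - xx[0])
    return inj


def _stationary_density(
    xx: np.ndarray, gamma: float, nu: float, theta: float
) -> np.ndarray:
    """Exact stationary solution of the discrete operator (L phi = -inj)."""
    lower, diag, upper, _ = _operator(xx, gamma, nu)
    n = len(xx)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    # absorbing boundaries
    ab[1, 0] = 1.0
    ab[0, 1] = 0.0
    ab[1, -1] = 1.0
    ab[2, -2] = 0.0
    rhs = -_injection(xx, theta)
    rhs[0] = 0.0
    rhs[-1] = 0.0
    return solve_banded((1, 1), ab, rhs)


def _sfs_from_density(xx: np.ndarray, phi: np.ndarray, n: int) -> np.ndarray:
    lb = _log_binom(n)
    i = np.arange(1, n)[:, None]
    kern = np.exp(lb[:, None] + i * np.log(np.maximum(xx, 1e-300))[None, :]
                  + (n - i) * np.log1p(-np.minimum(xx, 1 - 1e-16))[None, :])
    return np.trapezoid(kern * phi[None, :], xx, axis=1)


def expected_sfs_two_epoch(
    gamma: float,
    demography: DemographyModel,
    n: int,
    *,
    grid_points: int = 400,
    dt: float = 1e-3,
) -> np.ndarray:
    """Expected unfolded SFS under the two-epoch model at selection ``gamma``.

    The frequency density starts at the ancestral stationary solution
    (relative size ``omega``) and is evolved for scaled time ``tau`` at the
    current size with implicit Euler steps; binomial sampling to n
    chromosomes yields the SFS. omega = 1 (or tau = 0) reproduces the
    equilibrium spectrum; |gamma| beyond ``STRONG_SELECTION_GAMMA`` falls
    back to the equilibrium closed form.
    """
    if n < 2:
        raise InputError("n must be >= 2")
    theta = demography.theta
    if abs(gamma) >= STRONG_SELECTION_GAMMA:
        return expected_sfs_equilibrium(gamma, n, theta)
    xx = frequency_grid(grid_points)
    phi = _stationary_density(xx, gamma, demography.omega, theta)
    tau = demography.tau
    if tau > 0.0 and demography.omega != 1.0:
        lower, diag, upper, _ = _operator(xx, gamma, 1.0)
        inj = _injection(xx, theta)
        nsteps = max(1, int(np.ceil(tau / dt)))
        step = tau / nsteps
        npts = len(xx)
        ab = np.zeros((3, npts))
        ab[0, 1:] = -step * upper[:-1]
        ab[1, :] = 1.0 - step * diag
        ab[2, :-1] = -step * lower[1:]
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        for _ in range(nsteps):
            rhs = phi + step * inj
            rhs[0] = 0.0
            rhs[-1] = 0.0
            phi = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(phi)):
            raise FloatingPointError(
                f"diffusion step unstable (gamma={gamma}, dt={dt}, "
                f"grid={grid_points}); refine dt or grid"
            )
    return _sfs_from_density(xx, phi, n)


# ---------------------------------------------------------------------------
# Gamma DFE integration
# ---------------------------------------------------------------------------

def _per_s_sfs(
    s: float,
    demography: DemographyModel,
    n: int,
    ne: float,
    scaling: float,
    grid_points: int,
    dt: float,
) -> np.ndarray:
    gamma = -scaling * ne * s
    if demography.is_equilibrium:
        return expected_sfs_equilibrium(gamma, n, demography.theta)
    return expected_sfs_two_epoch(gamma, demography, n,
                                  grid_points=grid_points, dt=dt)


def integrate_gamma_dfe(
    dfe: GammaDFE,
    demography: DemographyModel,
    n: int,
    ne: float | None = None,
    *,
    scaling: float = 4.0,
    s_min: float = 1e-8,
    s_max: float = 1.0,
    n_nodes: int = 48,
    rtol: float = 1e-4,
    max_doublings: int = 4,
    grid_points: int = 400,
    dt: float = 1e-3,
) -> np.ndarray:
    """Expected SFS under a gamma DFE: E[xi_i] = Int E[xi_i | s] g(s) ds.

    Gauss-Legendre quadrature in log s on [s_min, s_max], with the node count
    doubled until successive estimates agree to ``rtol`` (relative, on the
    summed spectrum). Mass below s_min contributes the neutral spectrum; mass
    above s_max is effectively lethal and contributes no polymorphism.
    """
    if ne is None:
        ne = demography.ne
    dist = dfe.distribution()
    neutral_mass = dist.cdf(s_min)
    neutral = expected_sfs_equilibrium(0.0, n, demography.theta) \
        if demography.is_equilibrium else \
        expected_sfs_two_epoch(0.0, demography, n, grid_points=grid_points, dt=dt)

    cache: dict[float, np.ndarray] = {}

    def node_sfs(s: float) -> np.ndarray:
        if s not in cache:
            cache[s] = _per_s_sfs(s, demography, n, ne, scaling, grid_points, dt)
        return cache[s]

    # restrict the quadrature to where the DFE actually has mass
    lo_s = max(s_min, float(dist.ppf(1e-12)))
    hi_s = min(s_max, float(dist.isf(1e-12)))
    if not lo_s < hi_s:
        lo_s, hi_s = s_min, s_max
    neutral_mass = dist.cdf(lo_s)
    lo, hi = np.log(lo_s), np.log(hi_s)
    prev = None
    m = n_nodes
    for _ in range(max_doublings + 1):
        nodes, weights = np.polynomial.legendre.leggauss(m)
        u = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        s_vals = np.exp(u)
        dens = dist.pdf(s_vals) * s_vals  # Jacobian of u = log s
        est = np.zeros(n - 1)
        for s, d, w in zip(s_vals, dens, weights):
            if d > 0:
                est += w * d * node_sfs(float(s))
        est *= 0.5 * (hi - lo)
        if prev is not None:
            denom = max(prev.sum(), 1e-300)
            if abs(est.sum() - prev.sum()) / denom < rtol:
                prev = est
                break
        prev = est
        m *= 2
    else:
        raise FloatingPointError("gamma-DFE quadrature did not converge")
    return prev + neutral_mass * neutral


class SelectionSpectrumCache:
    """Per-s expected spectra on a fixed log grid, for fast DFE likelihoods.

    Builds E[xi_i | s] once for each s on a dense log-spaced grid (given the
    demography and sample size); a (shape, rate) evaluation is then a
    trapezoid integral over the grid with gamma-density weights. The cached
    spectra are unit-theta.
    """

    def __init__(
        self,
        demography: DemographyModel,
        n: int,
        ne: float | None = None,
        *,
        scaling: float = 4.0,
        s_min: float = 1e-8,
        s_max: float = 1.0,
        n_grid: int = 160,
        grid_points: int = 300,
        dt: float = 2e-3,
    ) -> None:
        self.demography = demography
        self.n = n
        self.ne = demography.ne if ne is None else ne
        self.scaling = scaling
        unit = DemographyModel(demography.ne, demography.omega,
                               demography.tau, theta=1.0)
        self.s_grid = np.exp(np.linspace(np.log(s_min), np.log(s_max), n_grid))
        self.neutral = (
            expected_sfs_equilibrium(0.0, n, 1.0) if unit.is_equilibrium
            else expected_sfs_two_epoch(0.0, unit, n,
                                        grid_points=grid_points, dt=dt)
        )
        self.spectra = np.array([
            _per_s_sfs(float(s), unit, n, self.ne, scaling, grid_points, dt)
            for s in self.s_grid
        ])

    def expected_sfs(self, dfe: GammaDFE, theta: float = 1.0) -> np.ndarray:
        """Unit-theta expected SFS under ``dfe``, scaled by ``theta``."""
        dist = dfe.distribution()
        dens = dist.pdf(self.s_grid) * self.s_grid  # d s -> d log s
        log_s = np.log(self.s_grid)
        est = np.trapezoid(dens[:, None] * self.spectra, log_s, axis=0)
        est += dist.cdf(self.s_grid[0]) * self.neutral
        return theta * est
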