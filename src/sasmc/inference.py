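"""Surrogate-accelerated Bayesian estimation of (Z_eff, kappa^-1).

A measured (or pseudo-experimental) curve D with uncertainties sigma is
compared against surrogate predictions F through the chi-square
log-likelihood

    log L(theta) = -1/2 * sum_k (F_k(theta) - D_k)^2 / sigma_k^2

under uniform priors over the training box.  The posterior is sampled
with emcee's affine-invariant ensemble sampler; the result carries the
maximum a posteriori estimate (optionally refined by local optimization
of the smooth surrogate posterior), central credible intervals, a
split-chain R-hat convergence diagnostic and corner-plot summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import emcee

from .dataset import PARAM_BOUNDS
from .models import SurrogateModel, _match_grid
from .scattering import SAXSCurve

__all__ = [
    "PriorBox",
    "SamplerConfig",
    "PosteriorSamples",
    "MAPEstimate",
    "PosteriorSummary",
    "chi2_log_likelihood",
    "log_posterior",
    "run_mcmc",
    "map_estimate",
    "posterior_summary",
]

#: Default relative uncertainty assumed for curves without a sigma column.
DEFAULT_SIGMA_FRACTION = 0.02


@dataclass(frozen=True)
class PriorBox:
    """Uniform prior support; defaults to the training parameter box."""

    z_eff_bounds: tuple[float, float] = PARAM_BOUNDS[0]
    kappa_inv_bounds: tuple[float, float] = PARAM_BOUNDS[1]

    def __post_init__(self):
        for lo, hi in (self.z_eff_bounds, self.kappa_inv_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("prior bounds must be finite with lower < upper")

    def contains(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized membership test for (..., 2) parameter arrays."""
        theta = np.asarray(theta, dtype=float)
        (z_lo, z_hi), (k_lo, k_hi) = self.z_eff_bounds, self.kappa_inv_bounds
        return ((theta[..., 0] >= z_lo) & (theta[..., 0] <= z_hi)
                & (theta[..., 1] >= k_lo) & (theta[..., 1] <= k_hi))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        (z_lo, z_hi), (k_lo, k_hi) = self.z_eff_bounds, self.kappa_inv_bounds
        out = np.empty((n, 2))
        out[:, 0] = rng.uniform(z_lo, z_hi, n)
        out[:, 1] = rng.uniform(k_lo, k_hi, n)
        return out


@dataclass
class SamplerConfig:
    n_walkers: int = 32
    n_steps: int = 5000
    burn_in_fraction: float = 0.2
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_walkers < 8:
            raise ValueError("ensemble sampling needs at least 8 walkers")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass
class PosteriorSamples:
    """Flattened MCMC chain over (z_eff, kappa_inv)."""

    samples: np.ndarray        # (M, 2)
    log_posterior: np.ndarray  # (M,)
    n_walkers: int
    n_steps: int
    burn_in: int
    thin: int
    seed: int
    rhat: np.ndarray = field(default_factory=lambda: np.array([np.nan, np.nan]))
    converged: bool = True
    acceptance_fraction: float = np.nan


@dataclass
class MAPEstimate:
    z_eff: float
    kappa_inv: float
    #: {"z_eff": {68: (lo, hi), 95: (lo, hi)}, "kappa_inv": {...}}
    credible_intervals: dict
    log_posterior: float


@dataclass
class PosteriorSummary:
    """Corner-plot data: 1-D marginals, 2-D density, Pearson correlation."""

    edges_z: np.ndarray
    density_z: np.ndarray
    edges_k: np.ndarray
    density_k: np.ndarray
    density_2d: np.ndarray
    correlation: float


def _data_sigma(data: SAXSCurve,
                sigma_fraction: float = DEFAULT_SIGMA_FRACTION) -> np.ndarray:
    """Per-point sigma; defaults to a fractional uncertainty when absent."""
    if data.sigma is not None:
        if np.any(data.sigma <= 0):
            raise ValueError("sigma must be positive")
        return data.sigma
    return sigma_fraction * data.intensity


def chi2_log_likelihood(params, data: SAXSCurve, surrogate: SurrogateModel,
                        sigma_fraction: float = DEFAULT_SIGMA_FRACTION):
    """-1/2 chi^2 between the surrogate curve(s) and the data.

    When the surrogate carries a validation-estimated
    ``model_error_fraction``, that emulator uncertainty is added to the
    measurement sigma in quadrature -- comparing data against an
    imperfect emulator at the bare measurement sigma would overstate the
    information content of the fit.  ``params`` may be one pair or a
    batch (k, 2); the return matches.
    """
    theta = np.asarray(params, dtype=float)
    d = _match_grid(data.q, surrogate.q, data.intensity)
    sigma = _match_grid(data.q, surrogate.q, _data_sigma(data, sigma_fraction))
    f = surrogate.predict_curve(theta)
    model_err = getattr(surrogate, "model_error_fraction", None)
    if model_err is not None:
        sigma = np.sqrt(sigma ** 2 + (model_err * f) ** 2)
    chi2 = np.sum(((f - d) / sigma) ** 2, axis=-1)
    return -0.5 * chi2


def log_posterior(params, data: SAXSCurve, surrogate: SurrogateModel,
                  prior: PriorBox | None = None,
                  sigma_fraction: float = DEFAULT_SIGMA_FRACTION):
    """Log posterior up to a constant: -inf outside the (closed) prior box."""
    prior = prior or PriorBox()
    theta = np.asarray(params, dtype=float)
    scalar = theta.ndim == 1
    theta = np.atleast_2d(theta)
    out = np.full(theta.shape[0], -np.inf)
    inside = prior.contains(theta)
    if np.any(inside):
        out[inside] = chi2_log_likelihood(theta[inside], data, surrogate,
                                          sigma_fraction)
    return out[0] if scalar else out


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction; chain is (steps, walkers, dim)."""
    n, w, dim = chain.shape
    half = n // 2
    segments = np.concatenate([chain[:half], chain[half:2 * half]], axis=1)
    means = segments.mean(axis=0)              # (2w, dim)
    variances = segments.var(axis=0, ddof=1)   # (2w, dim)
    within = variances.mean(axis=0)
    between = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * within + between / half
    return np.sqrt(var_plus / within)


def run_mcmc(data: SAXSCurve, surrogate: SurrogateModel,
             prior: PriorBox | None = None,
             config: SamplerConfig | None = None,
             sigma_fraction: float = DEFAULT_SIGMA_FRACTION,
             ) -> PosteriorSamples:
    """Affine-invariant ensemble sampling of the (Z_eff, kappa^-1) posterior.

    Walkers start uniformly in the prior box; the first
    ``burn_in_fraction`` of steps is discarded and the retained chain is
    thinned by ``config.thin``.  Non-convergence (split R-hat >= 1.05) is
    reported through ``converged``/``rhat`` rather than raised.
    """
    prior = prior or PriorBox()
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)

    def log_prob(theta):
        return log_posterior(theta, data, surrogate, prior, sigma_fraction)

    p0 = prior.sample(config.n_walkers, rng)
    sampler = emcee.EnsembleSampler(config.n_walkers, 2, log_prob,
                                    vectorize=True)
    sampler._random = np.random.RandomState(config.seed)
    sampler.run_mcmc(p0, config.n_steps, progress=False)
    burn = int(config.burn_in_fraction * config.n_steps)
    chain = sampler.get_chain(discard=burn, thin=config.thin)
    logp = sampler.get_log_prob(discard=burn, thin=config.thin)
    rhat = _split_rhat(chain)
    return PosteriorSamples(
        samples=chain.reshape(-1, 2),
        log_posterior=logp.reshape(-1),
        n_walkers=config.n_walkers, n_steps=config.n_steps,
        burn_in=burn, thin=config.thin, seed=config.seed,
        rhat=rhat, converged=bool(np.all(rhat < 1.05)),
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)))


def map_estimate(posterior: PosteriorSamples,
                 data: SAXSCurve | None = None,
                 surrogate: SurrogateModel | None = None,
                 prior: PriorBox | None = None,
                 refine: bool = False,
                 sigma_fraction: float = DEFAULT_SIGMA_FRACTION) -> MAPEstimate:
    """MAP = retained sample of maximal log posterior, plus central CIs.

    With ``refine=True`` (requires ``data`` and ``surrogate``) the sample
    argmax seeds a Nelder-Mead polish of the smooth surrogate posterior.
    """
    if posterior.samples.shape[0] == 0:
        raise ValueError("empty chain")
    if posterior.samples.shape[0] < 1000:
        raise ValueError("need at least 1000 retained samples for a MAP")
    best = int(np.argmax(posterior.log_posterior))
    theta = posterior.samples[best].copy()
    logp = float(posterior.log_posterior[best])
    if refine:
        if data is None or surrogate is None:
            raise ValueError("refinement needs the data and the surrogate")
        from scipy.optimize import minimize

        def neg(t):
            return -float(log_posterior(t, data, surrogate, prior,
                                        sigma_fraction))

        res = minimize(neg, theta, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6})
        if np.isfinite(res.fun) and -res.fun >= logp:
            theta, logp = res.x, -float(res.fun)
    intervals = {}
    for k, name in enumerate(("z_eff", "kappa_inv")):
        col = posterior.samples[:, k]
        intervals[name] = {
            68: tuple(np.percentile(col, [16.0, 84.0])),
            95: tuple(np.percentile(col, [2.5, 97.5])),
        }
    return MAPEstimate(float(theta[0]), float(theta[1]), intervals, logp)


def posterior_summary(posterior: PosteriorSamples, n_bins: int = 40,
                      prior: PriorBox | None = None) -> PosteriorSummary:
    """Histograms on fixed bins inside the prior box + Pearson correlation."""
    z = posterior.samples[:, 0]
    k = posterior.samples[:, 1]
    if prior is not None:
        z_range, k_range = prior.z_eff_bounds, prior.kappa_inv_bounds
    else:
        z_range = (z.min(), z.max())
        k_range = (k.min(), k.max())
    density_z, edges_z = np.histogram(z, bins=n_bins, range=z_range,
                                      density=True)
    density_k, edges_k = np.histogram(k, bins=n_bins, range=k_range,
                                      density=True)
    density_2d, _, _ = np.histogram2d(z, k, bins=n_bins,
                                      range=[z_range, k_range], density=True)
    corr = float(np.corrcoef(z, k)[0, 1])
    return PosteriorSummary(edges_z, density_z, edges_k, density_k,
                            density_2d, corr)
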