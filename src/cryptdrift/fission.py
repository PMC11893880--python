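"""Hierarchical Bayesian inference of crypt-fission rates from patch censuses.

Conditional on a patch being observed at age ``t`` in a patient with fission
rate ``rho``, its size follows the logarithmic-series distribution

    P(n) = q^n / (n * (-ln(1 - q))),   q = 1 - exp(-rho t),

obtained by normalising the patch-size law F_n(t) = dCfix (1-e^{-rho t})^n /
(rho n): the fixation slope cancels, so patch sizes alone identify rho.
Patient-to-patient variability is modelled by a Student-t hierarchy

    rho_i ~ StudentT(nu, mu, sigma)      (truncated to rho_i > 0)
    mu    ~ Normal(0, 0.01)  truncated to mu >= 0
    sigma ~ HalfNormal(0.01)
    nu    ~ Gamma(shape=2, rate=0.1)

whose heavy tails (small nu) absorb outlier patients, including regimes
where the population variance is not well defined. Prior widths are read as
standard deviations / a Gamma rate and are config-exposed. Sampling is by
adaptive Metropolis-within-Gibbs: all patient rates update in one vectorised
elementwise step (they are conditionally independent given the population
parameters), followed by scalar updates of mu, log sigma and log nu.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, stdtr
from scipy.stats import logser

from ._mcmc import ConvergenceError, InferenceConfig, split_rhat
from .census import CloneCensus

__all__ = [
    "FissionHierarchy",
    "logseries_q",
    "patch_size_loglik",
    "fit_fission_hierarchy",
]


def logseries_q(rho: float, age: float) -> float:
    """Logarithmic-series parameter q = 1 - exp(-rho * age), in [0, 1)."""
    if rho < 0 or age < 0:
        raise ValueError("rho and age must be non-negative")
    return float(-np.expm1(-rho * age))


def patch_size_loglik(sizes, age: float, rho: float) -> float:
    """Log-likelihood of observed patch sizes under the logarithmic-series law.

    Conditions on the patches that were observed; the fixation slope cancels
    in the normalisation, so the result depends only on ``rho * age``.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0:
        return 0.0
    if np.any(sizes < 1):
        raise ValueError("patch sizes must be >= 1")
    if rho <= 0 or age <= 0:
        raise ValueError("patch_size_loglik requires rho > 0 and age > 0")
    q = logseries_q(rho, age)
    return float(np.sum(logser.logpmf(sizes, q)))


def logseries_mean(q: float) -> float:
    """Mean patch size of the logarithmic-series law, -q / ((1-q) ln(1-q))."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return -q / ((1.0 - q) * math.log1p(-q))


@dataclass
class FissionHierarchy:
    """Posterior summary of the fission hierarchy.

    Draws are stored per chain; summaries pool chains. ``mu`` is the
    population location of the fission rate (per year); in the "log"
    parameterisation it is reported as exp(location), the population median
    rate.
    """

    mu_mean: float
    mu_ci95: tuple[float, float]
    sigma_mean: float
    nu_mean: float
    rho_mean: dict[str, float]
    rhat: float
    seed: int
    mu_draws: np.ndarray = field(repr=False)  # (chains, draws)
    sigma_draws: np.ndarray = field(repr=False)
    nu_draws: np.ndarray = field(repr=False)
    rho_draws: np.ndarray = field(repr=False)  # (chains, draws, patients)
    patient_ids: list[str] = field(repr=False)

    def summary_dict(self) -> dict:
        return {
            "mu_mean": self.mu_mean,
            "mu_ci95": list(self.mu_ci95),
            "sigma_mean": self.sigma_mean,
            "nu_mean": self.nu_mean,
            "rho_i": self.rho_mean,
            "rhat": self.rhat,
            "seed": self.seed,
        }


def _t_logpdf(x, nu, mu, sigma):
    """Student-t log density, vectorised (no scipy.stats overhead)."""
    z = (x - mu) / sigma
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


def _patch_loglik_matrix(rho, ages, k_patches, s_crypts):
    """Σ_i patch log-likelihood at rho (chains x patients), up to the
    rho-independent -Σ log(size) constant which cancels in every Metropolis
    ratio."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x = rho * ages  # broadcasts (C, P)
        return s_crypts * np.log(-np.expm1(-x)) - k_patches * np.log(x)


def fit_fission_hierarchy(
    censuses: list[CloneCensus],
    config: InferenceConfig | None = None,
    prior_only: bool = False,
) -> FissionHierarchy:
    """Fit the Student-t fission hierarchy to patch censuses by MCMC.

    Patients without patches carry no patch-size information and are
    dropped (patch *number* is informative about the fixation slope, which
    is inferred separately in clone_dynamics). Requires >= 2 contributing
    patients. Raises :class:`ConvergenceError` if split-R-hat on the
    population location exceeds the configured threshold.

    ``prior_only=True`` drops the likelihood (prior-predictive diagnostic).
    """
    config = config or InferenceConfig()
    contributing = [c for c in censuses if c.n_clones > 0]
    if len(contributing) < 2:
        raise ValueError("need >= 2 patients contributing >= 1 patch each")
    if all(all(s == 1 for s in c.patch_sizes) for c in contributing):
        warnings.warn(
            "all patches have size 1: the fission rate is weakly identified "
            "and the posterior will concentrate near zero / the prior",
            stacklevel=2,
        )

    ids = [c.patient_id for c in contributing]
    ages = np.array([c.age for c in contributing])
    k_patches = np.array([float(c.n_clones) for c in contributing])
    s_crypts = np.array([float(sum(c.patch_sizes)) for c in contributing])
    n_pat = len(contributing)
    if prior_only:
        k_patches = np.zeros(n_pat)
        s_crypts = np.zeros(n_pat)

    log_mode = config.rate_transform == "log"
    rng = np.random.default_rng(config.seed)
    n_chains, n_warmup, n_draws = config.n_chains, config.n_warmup, config.n_draws

    # crude method-of-moments initialisation from the pooled mean patch size
    mean_size = float(np.sum(s_crypts) / max(np.sum(k_patches), 1.0))
    mean_age = float(np.mean(ages))
    q0 = min(max(1.0 - 1.0 / max(mean_size, 1.001), 0.02), 0.95)
    rho0 = -math.log1p(-q0) / mean_age

    if log_mode:
        mu = np.log(rho0) + 0.3 * rng.standard_normal(n_chains)
        sigma = np.exp(rng.normal(-1.0, 0.3, n_chains))
        prior_mu_scale, prior_sigma_scale = 5.0, 1.0
    else:
        mu = np.abs(rho0 * (1.0 + 0.3 * rng.standard_normal(n_chains))) + 1e-5
        sigma = config.sigma_prior_scale * np.exp(rng.normal(-0.7, 0.3, n_chains))
        prior_mu_scale, prior_sigma_scale = config.mu_prior_scale, config.sigma_prior_scale
    nu = config.nu_shape / config.nu_rate * np.exp(rng.normal(0.0, 0.2, n_chains))
    eta = (np.log(rho0) if log_mode else rho0) * np.ones((n_chains, n_pat))
    eta = eta + 0.1 * np.abs(eta) * rng.standard_normal((n_chains, n_pat))

    def rho_of(e):
        if log_mode:
            with np.errstate(over="ignore"):  # overflowing proposals get -inf and reject
                return np.exp(e)
        return e

    def hyper_logprior(mu_, sigma_, nu_):
        lp = -0.5 * (mu_ / prior_mu_scale) ** 2
        if not log_mode:
            lp = np.where(mu_ >= 0.0, lp, -np.inf)
        lp = lp - 0.5 * (sigma_ / prior_sigma_scale) ** 2 + np.log(sigma_)  # + log-Jacobian
        lp = lp + config.nu_shape * np.log(nu_) - config.nu_rate * nu_  # Gamma + log-Jacobian
        return lp

    def eta_logprior(e, nu_, mu_, sigma_):
        """t prior on the (possibly transformed) rates, per (chain, patient)."""
        lp = _t_logpdf(e, nu_[:, None], mu_[:, None], sigma_[:, None])
        if log_mode:
            return lp  # hierarchy is placed on eta = log rho itself; no Jacobian
        lp = np.where(e > 0.0, lp, -np.inf)
        return lp

    def trunc_const(nu_, mu_, sigma_):
        """-n_pat * log P(rho_i > 0 | hyper): truncation normalisation."""
        if log_mode:
            return np.zeros_like(mu_)
        return -n_pat * np.log(stdtr(nu_, mu_ / sigma_))

    def loglik(e):
        r = rho_of(e)
        ll = _patch_loglik_matrix(r, ages, k_patches, s_crypts)
        return np.where(r > 0.0, ll, -np.inf) if not log_mode else ll

    ll_cur = loglik(eta)

    step_eta = np.full((n_chains, n_pat), math.log(0.3 * max(rho0, 1e-4) if not log_mode else 0.3))
    step_mu = np.full(n_chains, math.log(0.3 * max(rho0, 1e-4) if not log_mode else 0.3))
    step_sig = np.full(n_chains, math.log(0.5))
    step_nu = np.full(n_chains, math.log(0.5))
    step_shift = np.full(n_chains, math.log(0.1 * max(rho0, 1e-4) if not log_mode else 0.1))
    step_scale = np.full(n_chains, math.log(0.3))
    step_ridge = np.full(n_chains, math.log(0.3))
    hyper_rounds = 3

    mu_out = np.empty((n_chains, n_draws))
    sig_out = np.empty((n_chains, n_draws))
    nu_out = np.empty((n_chains, n_draws))
    rho_out = np.empty((n_chains, n_draws, n_pat))

    for i in range(n_warmup + n_draws):
        adapt = i < n_warmup
        gain = (1.0 + 0.1 * i) ** -0.6

        # --- patient rates, elementwise ---
        prop = eta + np.exp(step_eta) * rng.standard_normal((n_chains, n_pat))
        ll_prop = loglik(prop)
        d = (ll_prop + eta_logprior(prop, nu, mu, sigma)) - (
            ll_cur + eta_logprior(eta, nu, mu, sigma)
        )
        acc = np.log(rng.random((n_chains, n_pat))) < d
        eta = np.where(acc, prop, eta)
        ll_cur = np.where(acc, ll_prop, ll_cur)
        if adapt:
            step_eta += (acc.astype(float) - 0.44) * gain

        # --- joint translation of (mu, all rates): the posterior's slow
        # direction, since the t prior ties the rates to the location ---
        delta = np.exp(step_shift) * rng.standard_normal(n_chains)
        prop_eta = eta + delta[:, None]
        prop_mu = mu + delta
        ll_prop = loglik(prop_eta)
        # t-prior terms are translation-invariant (z unchanged); only the
        # likelihood, the mu prior, support bounds and the truncation
        # normalisation move
        d = (
            ll_prop.sum(axis=1)
            + hyper_logprior(prop_mu, sigma, nu)
            + trunc_const(nu, prop_mu, sigma)
            - ll_cur.sum(axis=1)
            - hyper_logprior(mu, sigma, nu)
            - trunc_const(nu, mu, sigma)
        )
        acc = np.log(rng.random(n_chains)) < np.nan_to_num(d, nan=-np.inf)
        eta = np.where(acc[:, None], prop_eta, eta)
        mu = np.where(acc, prop_mu, mu)
        ll_cur = np.where(acc[:, None], ll_prop, ll_cur)
        if adapt:
            step_shift += (acc.astype(float) - 0.3) * gain

        # --- joint scale move: expand the rates about mu together with
        # sigma (the orthogonal ridge direction; the per-patient -log sigma
        # in the t density cancels the Jacobian of the rate expansion) ---
        c = np.exp(np.exp(step_scale) * rng.standard_normal(n_chains))
        prop_eta = mu[:, None] + (eta - mu[:, None]) * c[:, None]
        prop_sig = sigma * c
        ll_prop = loglik(prop_eta)
        d = (
            ll_prop.sum(axis=1)
            + hyper_logprior(mu, prop_sig, nu)
            + trunc_const(nu, mu, prop_sig)
            - ll_cur.sum(axis=1)
            - hyper_logprior(mu, sigma, nu)
            - trunc_const(nu, mu, sigma)
        )
        acc = np.log(rng.random(n_chains)) < np.nan_to_num(d, nan=-np.inf)
        eta = np.where(acc[:, None], prop_eta, eta)
        sigma = np.where(acc, prop_sig, sigma)
        ll_cur = np.where(acc[:, None], ll_prop, ll_cur)
        if adapt:
            step_scale += (acc.astype(float) - 0.3) * gain

        # --- population parameters given the rates: several rounds of a
        # ridge move (location traded against scale at fixed rates, with a
        # scale-mixture proposal whose occasional bold steps jump between
        # the high-mu/low-sigma bulk and the low-mu/heavy-tail mode) plus
        # scalar mu / sigma / nu updates; the conditional is only
        # 3-dimensional, so extra rounds are cheap and decorrelate it ---
        def hyper_target(mu_, sigma_, nu_):
            return (
                hyper_logprior(mu_, sigma_, nu_)
                + eta_logprior(eta, nu_, mu_, sigma_).sum(axis=1)
                + trunc_const(nu_, mu_, sigma_)
            )

        cur = hyper_target(mu, sigma, nu)
        for _ in range(hyper_rounds):
            bold = np.where(rng.random(n_chains) < 0.3, 8.0, 1.0)
            eps = np.exp(step_ridge) * bold * rng.standard_normal(n_chains)
            prop_sig = sigma * np.exp(eps)
            prop_mu = mu - (prop_sig - sigma)
            new = hyper_target(prop_mu, prop_sig, nu)
            acc = np.log(rng.random(n_chains)) < np.nan_to_num(new - cur, nan=-np.inf)
            mu = np.where(acc, prop_mu, mu)
            sigma = np.where(acc, prop_sig, sigma)
            cur = np.where(acc, new, cur)
            if adapt:
                step_ridge += (acc.astype(float) - 0.3) * gain

            prop_mu = mu + np.exp(step_mu) * rng.standard_normal(n_chains)
            new = hyper_target(prop_mu, sigma, nu)
            acc = np.log(rng.random(n_chains)) < np.nan_to_num(new - cur, nan=-np.inf)
            mu = np.where(acc, prop_mu, mu)
            cur = np.where(acc, new, cur)
            if adapt:
                step_mu += (acc.astype(float) - 0.44) * gain

            prop_sig = sigma * np.exp(np.exp(step_sig) * rng.standard_normal(n_chains))
            new = hyper_target(mu, prop_sig, nu)
            acc = np.log(rng.random(n_chains)) < np.nan_to_num(new - cur, nan=-np.inf)
            sigma = np.where(acc, prop_sig, sigma)
            cur = np.where(acc, new, cur)
            if adapt:
                step_sig += (acc.astype(float) - 0.44) * gain

            prop_nu = nu * np.exp(np.exp(step_nu) * rng.standard_normal(n_chains))
            new = hyper_target(mu, sigma, prop_nu)
            acc = np.log(rng.random(n_chains)) < np.nan_to_num(new - cur, nan=-np.inf)
            nu = np.where(acc, prop_nu, nu)
            cur = np.where(acc, new, cur)
            if adapt:
                step_nu += (acc.astype(float) - 0.44) * gain

            if not log_mode:
                # independence refresh of (mu, sigma) from their priors:
                # prior and proposal densities cancel, so the acceptance
                # ratio involves only the t terms — this makes rare
                # excursions into the prior's heavy-sigma region reversible
                prop_mu = np.abs(prior_mu_scale * rng.standard_normal(n_chains))
                prop_sig = np.abs(prior_sigma_scale * rng.standard_normal(n_chains)) + 1e-12
                d_ind = (
                    eta_logprior(eta, nu, prop_mu, prop_sig).sum(axis=1)
                    + trunc_const(nu, prop_mu, prop_sig)
                    - eta_logprior(eta, nu, mu, sigma).sum(axis=1)
                    - trunc_const(nu, mu, sigma)
                )
                acc = np.log(rng.random(n_chains)) < np.nan_to_num(d_ind, nan=-np.inf)
                mu = np.where(acc, prop_mu, mu)
                sigma = np.where(acc, prop_sig, sigma)
                cur = np.where(acc, hyper_target(mu, sigma, nu), cur)

        if not adapt:
            j = i - n_warmup
            mu_out[:, j] = np.exp(mu) if log_mode else mu
            sig_out[:, j] = sigma
            nu_out[:, j] = nu
            rho_out[:, j, :] = rho_of(eta)

    rhat = split_rhat(mu_out)
    if rhat > config.rhat_threshold:
        raise ConvergenceError(
            f"split-R-hat on the population fission rate is {rhat:.4f} "
            f"(threshold {config.rhat_threshold}); increase n_draws/n_warmup"
        )
    flat_mu = mu_out.ravel()
    lo, hi = np.percentile(flat_mu, [2.5, 97.5])
    return FissionHierarchy(
        mu_mean=float(flat_mu.mean()),
        mu_ci95=(float(lo), float(hi)),
        sigma_mean=float(sig_out.mean()),
        nu_mean=float(nu_out.mean()),
        rho_mean={pid: float(rho_out[:, :, k].mean()) for k, pid in enumerate(ids)},
        rhat=rhat,
        seed=config.seed,
        mu_draws=mu_out,
        sigma_draws=sig_out,
        nu_draws=nu_out,
        rho_draws=rho_out,
        patient_ids=ids,
    )
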