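"""Gibbs full conditionals of the change-point hierarchy.

Each conditional follows from standard conjugacy with the normal likelihood:

* theta_ik | rest: the likelihood contributes ``n_i`` normal observations of
  mean theta (after subtracting the change-point shift for active cases) and
  the prior is N(mu_theta_k, sigma_theta2_k), giving a normal with precision
  ``n_i / sigma2_k + 1 / sigma_theta2_k``.
* mu_theta_k | rest: normal-normal over the N subject baselines with
  N(mu0_k, sigma02_k) prior.
* sigma_theta2_k | rest: inverse-gamma, shape a + N/2, scale
  b + sum (theta - mu_theta)^2 / 2.
* mu_gamma_k, sigma_gamma2_k | rest: same normal-normal / inverse-gamma
  structure over the *active* log slopes (cases with I_ik = 1 only); with no
  active slope the conditional reduces to the prior.
* sigma2_k | rest: inverse-gamma over all residuals of marker k.

Helpers return the conditional's parameters so tests can compare the implied
density against a grid-normalised prior x likelihood evaluation.
"""

from __future__ import annotations

import numpy as np

from .hyperparams import Hyperparams
from .likelihood import PreparedData, case_mean_shift

__all__ = [
    "theta_conditional", "mu_theta_conditional", "sigma_theta2_conditional",
    "mu_gamma_conditional", "sigma_gamma2_conditional", "sigma2_conditional",
    "sample_inverse_gamma",
    "gibbs_update_theta", "gibbs_update_mu_theta", "gibbs_update_sigma_theta2",
    "gibbs_update_mu_gamma", "gibbs_update_sigma_gamma2", "gibbs_update_sigma2",
]


def sample_inverse_gamma(shape, scale, rng, size=None):
    """Draw from InvGamma(shape, scale) (density ~ x^-(a+1) exp(-b/x))."""
    return np.asarray(scale) / rng.gamma(shape, 1.0, size=size)


def _normal_normal(obs_sum, n_obs, obs_var, prior_mean, prior_var):
    """Posterior (mean, var) for a normal mean with known obs variance."""
    prec = n_obs / obs_var + 1.0 / prior_var
    var = 1.0 / prec
    mean = var * (obs_sum / obs_var + prior_mean / prior_var)
    return mean, var


# ---------------------------------------------------------------- conditionals

def _detrended_sums(prep: PreparedData, k: int, I, gamma, tau):
    """Per-subject sums of y - shift for marker k (controls shift 0)."""
    vals = prep.y[:, k].copy()
    if prep.n_cases:
        case_obs = prep.sub_flat >= prep.n0
        vals[case_obs] -= case_mean_shift(prep, k, I[:, k], gamma[:, k], tau[:, k])
    return np.bincount(prep.sub_flat, weights=vals, minlength=prep.N)


def theta_conditional(prep, k, state, hyper: Hyperparams):
    """(mean, var) vectors of the N independent theta_ik full conditionals."""
    sums = _detrended_sums(prep, k, state.I, state.gamma, state.tau)
    return _normal_normal(
        sums, prep.counts, state.sigma2[k],
        state.mu_theta[k], state.sigma_theta2[k],
    )


def mu_theta_conditional(prep, k, state, hyper: Hyperparams):
    return _normal_normal(
        state.theta[:, k].sum(), prep.N, state.sigma_theta2[k],
        hyper.mu0[k], hyper.sigma02[k],
    )


def sigma_theta2_conditional(prep, k, state, hyper: Hyperparams):
    resid = state.theta[:, k] - state.mu_theta[k]
    return (
        hyper.a_theta[k] + 0.5 * prep.N,
        hyper.b_theta[k] + 0.5 * float(resid @ resid),
    )


def mu_gamma_conditional(prep, k, state, hyper: Hyperparams):
    active = state.I[:, k] == 1
    lg = state.log_gamma[active, k]
    return _normal_normal(
        lg.sum(), lg.size, state.sigma_gamma2[k],
        hyper.mu1[k], hyper.sigma12[k],
    )


def sigma_gamma2_conditional(prep, k, state, hyper: Hyperparams):
    active = state.I[:, k] == 1
    resid = state.log_gamma[active, k] - state.mu_gamma[k]
    return (
        hyper.a_gamma[k] + 0.5 * resid.size,
        hyper.b_gamma[k] + 0.5 * float(resid @ resid),
    )


def sigma2_conditional(prep, k, state, hyper: Hyperparams):
    resid = prep.y[:, k] - state.theta[prep.sub_flat, k]
    if prep.n_cases:
        case_obs = prep.sub_flat >= prep.n0
        resid = resid.copy()
        resid[case_obs] -= case_mean_shift(
            prep, k, state.I[:, k], state.gamma[:, k], state.tau[:, k]
        )
    return (
        hyper.a_sigma[k] + 0.5 * prep.M,
        hyper.b_sigma[k] + 0.5 * float(resid @ resid),
    )


# -------------------------------------------------------------------- updates

def gibbs_update_theta(prep, k, state, hyper, rng):
    mean, var = theta_conditional(prep, k, state, hyper)
    state.theta[:, k] = rng.normal(mean, np.sqrt(var))


def gibbs_update_mu_theta(prep, k, state, hyper, rng):
    mean, var = mu_theta_conditional(prep, k, state, hyper)
    state.mu_theta[k] = rng.normal(mean, np.sqrt(var))


def gibbs_update_sigma_theta2(prep, k, state, hyper, rng):
    a, b = sigma_theta2_conditional(prep, k, state, hyper)
    state.sigma_theta2[k] = sample_inverse_gamma(a, b, rng)


def gibbs_update_mu_gamma(prep, k, state, hyper, rng):
    mean, var = mu_gamma_conditional(prep, k, state, hyper)
    state.mu_gamma[k] = rng.normal(mean, np.sqrt(var))


def gibbs_update_sigma_gamma2(prep, k, state, hyper, rng):
    a, b = sigma_gamma2_conditional(prep, k, state, hyper)
    state.sigma_gamma2[k] = sample_inverse_gamma(a, b, rng)


def gibbs_update_sigma2(prep, k, state, hyper, rng):
    a, b = sigma2_conditional(prep, k, state, hyper)
    state.sigma2[k] = sample_inverse_gamma(a, b, rng)
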