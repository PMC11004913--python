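"""Metropolis-Hastings and reversible-jump moves of the change-point sampler.

Coupling parameters (mu_I, eta_I)
    Random-walk MH on unbounded scales (mu_I directly, logit(eta_I)).  The
    target is the Beta priors times the MRF likelihood of all case indicator
    vectors, with the MRF normalising constant computed exactly by 2^K state
    enumeration, so the acceptance ratio is exact.

Indicators / slopes / change points (I_ik, gamma_ik, tau_ik)
    A trans-dimensional birth/death move per case and marker.  The birth
    proposal draws (log gamma, tau) from their priors, so proposal and prior
    densities cancel and the acceptance ratio reduces to the data likelihood
    ratio times the MRF conditional odds of I_ik = 1 given the patient's
    other indicators (the auto-logistic field F).  The death move is the
    exact reverse, so detailed balance holds with Jacobian 1.

    Because (gamma, tau) would otherwise change only at accepted births,
    active components are refreshed by within-model random walks on
    log gamma and tau (tau proposals outside the preclinical window are
    rejected outright).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit, logit

from .hyperparams import Hyperparams
from .likelihood import PreparedData
from .state import MCMCState
from ..mrf import mrf_log_normalizer

__all__ = [
    "coupling_log_posterior", "mh_update_coupling",
    "rj_update_marker", "refresh_active_marker", "rj_update_subject",
]


def _case_segment_sum(prep: PreparedData, values: np.ndarray) -> np.ndarray:
    """Sum an observation-level case array into per-case totals."""
    return np.bincount(prep.csub_flat, weights=values, minlength=prep.n_cases)


# ----------------------------------------------------------------- coupling MH

def coupling_log_posterior(mu_I: float, eta_I: float, I: np.ndarray,
                           hyper: Hyperparams) -> float:
    """log p(mu_I, eta_I | indicators), up to a constant.

    Beta priors expressed on the sampling scales (mu_I unbounded with
    logistic(mu_I) ~ Beta(p1,p2); eta_I in (0,1) via logit(eta_I)); the
    change-of-variable Jacobians shift the Beta exponents from (p-1) to p.
    """
    if not (0.0 < eta_I < 1.0):
        return -np.inf
    # logistic(mu_I) ~ Beta(p1, p2) -> density in mu_I propto m^p1 (1-m)^p2
    lp = hyper.p1 * log_expit(mu_I) + hyper.p2 * log_expit(-mu_I)
    x = logit(eta_I)
    lp += hyper.p3 * log_expit(x) + hyper.p4 * log_expit(-x)
    n_cases = I.shape[0]
    if n_cases:
        s1 = float(I.sum())
        s2 = float(np.einsum("nk,kl,nl->", I, hyper.R, I))
        lp += mu_I * s1 + eta_I * s2
        lp -= n_cases * mrf_log_normalizer(mu_I, eta_I, hyper.R)
    return float(lp)


def mh_update_coupling(state: MCMCState, hyper: Hyperparams, rng,
                       step_mu: float = 0.4, step_eta: float = 0.8):
    """One random-walk MH update of mu_I then eta_I; returns accept flags."""
    I = state.I.astype(float)
    lp_cur = coupling_log_posterior(state.mu_I, state.eta_I, I, hyper)

    mu_prop = state.mu_I + step_mu * rng.standard_normal()
    lp_prop = coupling_log_posterior(mu_prop, state.eta_I, I, hyper)
    acc_mu = np.log(rng.uniform()) < lp_prop - lp_cur
    if acc_mu:
        state.mu_I = float(mu_prop)
        lp_cur = lp_prop

    x_prop = logit(state.eta_I) + step_eta * rng.standard_normal()
    eta_prop = float(expit(x_prop))
    lp_prop = coupling_log_posterior(state.mu_I, eta_prop, I, hyper)
    acc_eta = np.log(rng.uniform()) < lp_prop - lp_cur
    if acc_eta:
        state.eta_I = eta_prop
    return bool(acc_mu), bool(acc_eta)


# ----------------------------------------------------------- reversible jump

def _conditional_field(state: MCMCState, hyper: Hyperparams, k: int) -> np.ndarray:
    """F_ik = mu_I + eta_I * sum_{k'!=k} S[k,k'] I_ik' per case (S = R + R^T)."""
    S = hyper.R + hyper.R.T
    neigh = state.I.astype(float) @ S[k] - S[k, k] * state.I[:, k]
    return state.mu_I + state.eta_I * neigh


def _delta_loglik(prep: PreparedData, k: int, theta_case: np.ndarray,
                  sigma2_k: float, shift: np.ndarray) -> np.ndarray:
    """Per-case log-likelihood gain of adding ``shift`` to the flat mean."""
    r = prep.y_case[:, k] - theta_case[prep.csub_flat]
    contrib = (r - shift) ** 2 - r**2
    return -_case_segment_sum(prep, contrib) / (2.0 * sigma2_k)


def _sample_tau_prior(prep: PreparedData, hyper: Hyperparams, rng) -> np.ndarray:
    from ..simulate import sample_truncated_changepoint

    return sample_truncated_changepoint(prep.d_case, hyper.mu_tau,
                                        hyper.sigma_tau2, hyper.tau_star, rng,
                                        size=prep.n_cases)


def rj_update_marker(prep: PreparedData, k: int, state: MCMCState,
                     hyper: Hyperparams, rng) -> None:
    """Birth/death reversible-jump proposal for every case at marker k.

    Patients are conditionally independent given (mu_I, eta_I), and only
    marker k of each patient changes, so the whole column updates in one
    vectorised pass.
    """
    if prep.n_cases == 0:
        return
    theta_case = state.theta[prep.n0:, k]
    sigma2_k = float(state.sigma2[k])
    F = _conditional_field(state, hyper, k)

    # prior-proposal birth values for every case (used where I == 0)
    lg_prop = rng.normal(state.mu_gamma[k], np.sqrt(state.sigma_gamma2[k]),
                         size=prep.n_cases)
    tau_prop = _sample_tau_prior(prep, hyper, rng)
    shift_prop = np.exp(lg_prop)[prep.csub_flat] * np.clip(
        prep.t_case - tau_prop[prep.csub_flat], 0.0, None
    )
    dll_prop = _delta_loglik(prep, k, theta_case, sigma2_k, shift_prop)

    # likelihood gain of the currently active components (used where I == 1)
    shift_cur = state.I[prep.csub_flat, k] * state.gamma[prep.csub_flat, k] * np.clip(
        prep.t_case - state.tau[prep.csub_flat, k], 0.0, None
    )
    dll_cur = _delta_loglik(prep, k, theta_case, sigma2_k, shift_cur)

    active = state.I[:, k] == 1
    log_alpha = np.where(active, -dll_cur - F, dll_prop + F)
    accept = np.log(rng.uniform(size=prep.n_cases)) < log_alpha

    births = accept & ~active
    deaths = accept & active
    state.I[births, k] = 1
    state.log_gamma[births, k] = lg_prop[births]
    state.tau[births, k] = tau_prop[births]
    state.I[deaths, k] = 0


def refresh_active_marker(prep: PreparedData, k: int, state: MCMCState,
                          hyper: Hyperparams, rng,
                          step_lg: float = 0.3, step_tau: float = 0.3) -> None:
    """Within-model random-walk refresh of (log gamma, tau) where I_ik = 1."""
    active = state.I[:, k] == 1
    if not active.any():
        return
    theta_case = state.theta[prep.n0:, k]
    sigma2_k = float(state.sigma2[k])
    c = prep.csub_flat

    def shifts(lg, tau):
        return (active.astype(float)[c] * np.exp(lg)[c]
                * np.clip(prep.t_case - tau[c], 0.0, None))

    # --- log gamma step
    lg_cur = state.log_gamma[:, k]
    lg_prop = lg_cur + step_lg * rng.standard_normal(prep.n_cases)
    dll = (_delta_loglik(prep, k, theta_case, sigma2_k, shifts(lg_prop, state.tau[:, k]))
           - _delta_loglik(prep, k, theta_case, sigma2_k,
                           shifts(lg_cur, state.tau[:, k])))
    prior = -((lg_prop - state.mu_gamma[k]) ** 2
              - (lg_cur - state.mu_gamma[k]) ** 2) / (2.0 * state.sigma_gamma2[k])
    acc = active & (np.log(rng.uniform(size=prep.n_cases)) < dll + prior)
    state.log_gamma[acc, k] = lg_prop[acc]

    # --- tau step (parent-normal prior; window truncation rejects outright)
    tau_cur = state.tau[:, k]
    tau_prop = tau_cur + step_tau * rng.standard_normal(prep.n_cases)
    in_window = (tau_prop > prep.d_case - hyper.tau_star) & (tau_prop < prep.d_case)
    dll = (_delta_loglik(prep, k, theta_case, sigma2_k,
                         shifts(state.log_gamma[:, k], tau_prop))
           - _delta_loglik(prep, k, theta_case, sigma2_k,
                           shifts(state.log_gamma[:, k], tau_cur)))
    mode = prep.d_case - hyper.mu_tau
    prior = -((tau_prop - mode) ** 2 - (tau_cur - mode) ** 2) / (2.0 * hyper.sigma_tau2)
    acc = active & in_window & (np.log(rng.uniform(size=prep.n_cases)) < dll + prior)
    state.tau[acc, k] = tau_prop[acc]


def rj_update_subject(prep: PreparedData, case_index: int, k: int,
                      state: MCMCState, hyper: Hyperparams, rng) -> None:
    """Single-subject birth/death move (scalar wrapper used by tests).

    Equivalent to the corresponding entry of :func:`rj_update_marker` but
    touching only one case.
    """
    keep = state.I[:, k].copy()
    keep_lg = state.log_gamma[:, k].copy()
    keep_tau = state.tau[:, k].copy()
    rj_update_marker(prep, k, state, hyper, rng)
    mask = np.ones(prep.n_cases, dtype=bool)
    mask[case_index] = False
    state.I[mask, k] = keep[mask]
    state.log_gamma[mask, k] = keep_lg[mask]
    state.tau[mask, k] = keep_tau[mask]
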