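"""Mutable sampler state for the change-point MCMC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from ..mrf import sample_indicators
from ..simulate import sample_truncated_changepoint
from .gibbs import sample_inverse_gamma
from .hyperparams import Hyperparams
from .likelihood import PreparedData

__all__ = ["MCMCState"]


@dataclass
class MCMCState:
    """All unknowns at one sweep.  ``gamma`` mirrors ``exp(log_gamma)``.

    Rows of ``I`` / ``log_gamma`` / ``tau`` index cases (0..n_cases-1);
    slope and change-point entries are meaningful only where ``I == 1`` but
    always hold valid values.
    """

    mu_theta: np.ndarray        # (K,)
    sigma_theta2: np.ndarray    # (K,)
    mu_gamma: np.ndarray        # (K,)
    sigma_gamma2: np.ndarray    # (K,)
    sigma2: np.ndarray          # (K,)
    mu_I: float
    eta_I: float
    theta: np.ndarray           # (N, K)
    I: np.ndarray               # (n_cases, K) int
    log_gamma: np.ndarray       # (n_cases, K)
    tau: np.ndarray             # (n_cases, K)

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma)

    @classmethod
    def from_prior(cls, prep: PreparedData, hyper: Hyperparams, rng) -> "MCMCState":
        """Initialise every unknown by a draw from its prior."""
        K, N, nc = prep.K, prep.N, prep.n_cases
        mu_theta = rng.normal(hyper.mu0, np.sqrt(hyper.sigma02))
        sigma_theta2 = sample_inverse_gamma(hyper.a_theta, hyper.b_theta, rng)
        mu_gamma = rng.normal(hyper.mu1, np.sqrt(hyper.sigma12))
        sigma_gamma2 = sample_inverse_gamma(hyper.a_gamma, hyper.b_gamma, rng)
        sigma2 = sample_inverse_gamma(hyper.a_sigma, hyper.b_sigma, rng)
        mu_I = float(logit(rng.beta(hyper.p1, hyper.p2)))
        eta_I = float(rng.beta(hyper.p3, hyper.p4))
        theta = rng.normal(mu_theta, np.sqrt(sigma_theta2), size=(N, K))
        if nc:
            I = sample_indicators(mu_I, eta_I, hyper.R, K, rng, size=nc)
            I = np.atleast_2d(I).astype(int)
            log_gamma = rng.normal(mu_gamma, np.sqrt(sigma_gamma2), size=(nc, K))
            tau = np.empty((nc, K))
            for k in range(K):
                tau[:, k] = sample_truncated_changepoint(
                    prep.d_case, hyper.mu_tau, hyper.sigma_tau2, hyper.tau_star, rng,
                    size=nc,
                )
        else:
            I = np.zeros((0, K), dtype=int)
            log_gamma = np.zeros((0, K))
            tau = np.zeros((0, K))
        return cls(
            mu_theta=mu_theta, sigma_theta2=sigma_theta2,
            mu_gamma=mu_gamma, sigma_gamma2=sigma_gamma2, sigma2=sigma2,
            mu_I=mu_I, eta_I=eta_I, theta=theta,
            I=I, log_gamma=log_gamma, tau=tau,
        )
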