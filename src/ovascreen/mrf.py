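"""Markov-random-field prior over a patient's change-point indicators.

The binary vector ``I = (I_1, ..., I_K)`` records which of a case's K
biomarkers exhibit a change point.  Its joint pmf is the auto-logistic form

    P(I) propto exp( mu_I * sum_k I_k  +  eta_I * I^T R I )

with R strictly upper triangular, so positive coupling ``eta_I`` makes a
change in one marker raise the conditional odds of a change in the others.
With ``eta_I = 0`` the indicators decouple into independent Bernoulli
variables with success probability ``logistic(mu_I)``.

For the small panels considered here (K <= 12) the normalising constant is
computed exactly by enumerating the 2^K states.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "default_coupling_matrix",
    "mrf_unnormalized_log_pmf",
    "mrf_log_normalizer",
    "mrf_log_pmf",
    "mrf_conditional_prob",
    "enumerate_states",
    "sample_indicators",
]

MAX_K = 12


def default_coupling_matrix(K: int) -> np.ndarray:
    """Strictly upper-triangular matrix of ones (every marker pair coupled)."""
    return np.triu(np.ones((K, K)), k=1)


def _check_R(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, np.triu(R, k=1)):
        raise ValueError("R must be strictly upper triangular")
    return R


def enumerate_states(K: int) -> np.ndarray:
    """All 2^K binary indicator vectors as a (2^K, K) array."""
    if K > MAX_K:
        raise ValueError(f"exact enumeration supported only for K <= {MAX_K}")
    bits = np.arange(2**K)[:, None] >> np.arange(K)[None, :]
    return (bits & 1).astype(float)


def mrf_unnormalized_log_pmf(I, mu_I: float, eta_I: float, R) -> np.ndarray:
    """log of the unnormalised mass; ``I`` may be one vector or a stack."""
    R = _check_R(R)
    I_arr = np.asarray(I, dtype=float)
    single = I_arr.ndim == 1
    I2 = np.atleast_2d(I_arr)
    val = mu_I * I2.sum(axis=1) + eta_I * np.einsum("nk,kl,nl->n", I2, R, I2)
    return float(val[0]) if single else val


def mrf_log_normalizer(mu_I: float, eta_I: float, R) -> float:
    R = _check_R(R)
    K = R.shape[0]
    states = enumerate_states(K)
    return float(logsumexp(mrf_unnormalized_log_pmf(states, mu_I, eta_I, R)))


def mrf_log_pmf(I, mu_I: float, eta_I: float, R) -> np.ndarray:
    """Exactly normalised log pmf (enumeration; K <= 12)."""
    return mrf_unnormalized_log_pmf(I, mu_I, eta_I, R) - mrf_log_normalizer(
        mu_I, eta_I, R
    )


def mrf_conditional_prob(I, k: int, mu_I: float, eta_I: float, R) -> float:
    """P(I_k = 1 | I_{k' != k}) = logistic(mu_I + eta_I * sum_{k'} S[k,k'] I_k').

    ``S = R + R^T`` symmetrises the upper-triangular coupling so each
    neighbour contributes once regardless of index order.
    """
    R = _check_R(R)
    I = np.asarray(I, dtype=float)
    S = R + R.T
    field = mu_I + eta_I * float(S[k] @ I - S[k, k] * I[k])
    return float(expit(field))


def sample_indicators(
    mu_I: float, eta_I: float, R, K: int, rng, size: int = 1
) -> np.ndarray:
    """Draw indicator vectors exactly from the MRF by state enumeration.

    Returns an array of shape (size, K) (or (K,) when ``size == 1``).
    """
    R = _check_R(R)
    if R.shape[0] != K:
        raise ValueError("R must be K x K")
    states = enumerate_states(K)
    logp = mrf_unnormalized_log_pmf(states, mu_I, eta_I, R)
    p = np.exp(logp - logsumexp(logp))
    p /= p.sum()
    idx = rng.choice(len(states), size=size, p=p)
    out = states[idx].astype(int)
    return out[0] if size == 1 else out
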