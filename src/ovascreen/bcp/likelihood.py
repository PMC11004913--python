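"""Likelihood of the hierarchical change-point model and flattened data views.

On the transformed scale, a control's marker k fluctuates about theta_ik
with noise variance sigma2_k.  A case additionally carries a binary
indicator I_ik: when on, the mean becomes

    theta_ik + gamma_ik * (t_ij - tau_ik)_+

with the positive-part kink at the change point tau_ik.  The log-likelihood
is the sum of normal log densities of the residuals (1/sigma Jacobian
included).

``PreparedData`` flattens a cohort into observation-level arrays so the
Gibbs blocks and reversible-jump moves can run as vectorised segment sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cohort import Cohort

__all__ = ["PreparedData", "case_mean_shift", "log_likelihood", "normal_logpdf_sum"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PreparedData:
    """Observation-flat view of a cohort (controls first, then cases).

    Attributes
    ----------
    y : (M, K) transformed levels for all M visit-observations
    t_flat : (M,) visit ages
    sub_flat : (M,) subject index (0..N-1) per observation
    counts : (N,) visits per subject
    d : (N,) age at last measurement per subject
    case-view arrays (suffix ``_case``) restrict to observations of cases,
    with ``csub_flat`` indexing cases 0..n_cases-1.
    """

    K: int
    N: int
    n0: int
    n_cases: int
    marker_names: list
    y: np.ndarray
    t_flat: np.ndarray
    sub_flat: np.ndarray
    counts: np.ndarray
    d: np.ndarray
    y_case: np.ndarray
    t_case: np.ndarray
    csub_flat: np.ndarray
    case_counts: np.ndarray
    d_case: np.ndarray

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "PreparedData":
        markers = list(cohort.biomarker_names)
        K = len(markers)
        N = cohort.n_patients
        n0 = cohort.n_controls
        n_cases = cohort.n_cases
        t_parts, y_parts, sub_parts = [], [], []
        counts = np.zeros(N, dtype=int)
        d = np.zeros(N)
        for i, p in enumerate(cohort.patients):
            T = p.n_visits
            counts[i] = T
            d[i] = p.d
            t_parts.append(p.ages)
            sub_parts.append(np.full(T, i, dtype=int))
            y_parts.append(np.column_stack([p.transformed(m) for m in markers]))
        t_flat = np.concatenate(t_parts)
        sub_flat = np.concatenate(sub_parts)
        y = np.vstack(y_parts)
        case_obs = sub_flat >= n0
        return cls(
            K=K, N=N, n0=n0, n_cases=n_cases, marker_names=markers,
            y=y, t_flat=t_flat, sub_flat=sub_flat, counts=counts, d=d,
            y_case=y[case_obs], t_case=t_flat[case_obs],
            csub_flat=sub_flat[case_obs] - n0,
            case_counts=counts[n0:], d_case=d[n0:],
        )

    @property
    def M(self) -> int:
        return self.t_flat.size


def case_mean_shift(prep: PreparedData, k: int, I, gamma, tau) -> np.ndarray:
    """Per-case-observation mean shift I * gamma * (t - tau)_+ for marker k.

    ``I``, ``gamma``, ``tau`` are per-case vectors (length n_cases); returns
    an array aligned with ``prep.t_case``.
    """
    c = prep.csub_flat
    active = np.asarray(I, dtype=float)[c]
    return active * np.asarray(gamma)[c] * np.clip(
        prep.t_case - np.asarray(tau)[c], 0.0, None
    )


def normal_logpdf_sum(resid: np.ndarray, sigma2: float) -> float:
    """Sum of N(0, sigma2) log densities of the residuals."""
    n = resid.size
    return float(-0.5 * n * (_LOG_2PI + np.log(sigma2))
                 - 0.5 * np.dot(resid, resid) / sigma2)


def log_likelihood(prep: PreparedData, theta, sigma2, I, gamma, tau) -> float:
    """Full-data log-likelihood.

    Parameters
    ----------
    theta : (N, K) subject baselines
    sigma2 : (K,) noise variances
    I : (n_cases, K) binary indicators
    gamma : (n_cases, K) post-change slopes (rows with I=0 ignored)
    tau : (n_cases, K) change-point ages (rows with I=0 ignored)
    """
    theta = np.asarray(theta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    total = 0.0
    case_obs = prep.sub_flat >= prep.n0
    for k in range(prep.K):
        resid = prep.y[:, k] - theta[prep.sub_flat, k]
        shift_full = np.zeros(prep.M)
        if prep.n_cases:
            shift_full[case_obs] = case_mean_shift(
                prep, k, I[:, k], gamma[:, k], tau[:, k]
            )
        total += normal_logpdf_sum(resid - shift_full, float(sigma2[k]))
    return total
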