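"""Posterior-predictive screening: case/control predictive densities and risk.

A new patient's longitudinal series (all modelled markers, visits up to the
current screen) is scored by the ratio of its predictive densities under the
control hypothesis (flat subject mean) and the case hypothesis (MRF mixture
over change-point configurations), combined with a prevalence prior via
Bayes' rule.

The subject baseline theta is integrated out analytically: conditional on a
population draw, the T visits of marker k are jointly normal with mean
mu_theta_k (plus the change-point shift under the case hypothesis) and
covariance sigma2_k * I + sigma_theta2_k * J, handled in closed form via the
rank-one structure.  Under the case hypothesis the indicator configuration
is mixed exactly over the 2^K MRF states per retained draw, while one Monte
Carlo draw of (log gamma, tau) per retained draw and marker integrates the
slope and change point.  Averaging across retained draws uses log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ..cohort import VisitSeries, Cohort
from ..mrf import enumerate_states
from .hyperparams import MU_TAU, SIGMA_TAU2, TAU_STAR
from .model import PosteriorSamples

__all__ = ["PrevalencePrior", "posterior_predictive_logdensity", "bayes_risk", "risk_score",
           "risk_trajectory", "score_cohort"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PrevalencePrior:
    """Prior disease prevalence; scalar or looked up by age band.

    ``table`` rows: (age_lo, age_hi, prevalence), half-open bands
    [age_lo, age_hi).  A scalar fallback applies outside every band.
    """

    scalar: float
    table: pd.DataFrame | None = None

    def __post_init__(self):
        if not 0.0 < self.scalar < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @classmethod
    def from_scalar(cls, p: float) -> "PrevalencePrior":
        return cls(scalar=float(p))

    @classmethod
    def from_age_bands(cls, table: pd.DataFrame,
                       fallback: float) -> "PrevalencePrior":
        required = {"age_lo", "age_hi", "prevalence"}
        if not required.issubset(table.columns):
            raise ValueError(f"table needs columns {required}")
        return cls(scalar=float(fallback), table=table.reset_index(drop=True))

    def __call__(self, age: float | None = None) -> float:
        if self.table is not None and age is not None:
            hit = self.table[(self.table.age_lo <= age) & (age < self.table.age_hi)]
            if len(hit):
                return float(hit["prevalence"].iloc[0])
        return self.scalar


def _as_prevalence(prevalence) -> PrevalencePrior:
    if isinstance(prevalence, PrevalencePrior):
        return prevalence
    return PrevalencePrior.from_scalar(float(prevalence))


def _series_arrays(series: VisitSeries, marker_names) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(series.ages, dtype=float)
    Y = np.column_stack([series.transformed(m) for m in marker_names])
    return t, Y


def _rank_one_normal_logpdf(resid, sigma2, s2):
    """log N(resid; 0, sigma2 I + s2 J) along the last axis (length T).

    Uses det = sigma2^(T-1) (sigma2 + T s2) and the Sherman-Morrison inverse.
    """
    T = resid.shape[-1]
    tot = sigma2 + T * s2
    quad = (np.sum(resid**2, axis=-1)
            - s2 * np.sum(resid, axis=-1) ** 2 / tot) / sigma2
    logdet = (T - 1) * np.log(sigma2) + np.log(tot)
    return -0.5 * (T * _LOG_2PI + logdet + quad)


def _thin_index(n: int, max_draws: int | None) -> np.ndarray:
    if max_draws is None or n <= max_draws:
        return np.arange(n)
    return np.linspace(0, n - 1, max_draws).astype(int)


def posterior_predictive_logdensity(series: VisitSeries,
                                    samples: PosteriorSamples,
                                    hypothesis: int,
                                    n_visits: int | None = None,
                                    seed: int = 0,
                                    max_draws: int | None = 2000,
                                    n_rep: int = 1) -> float:
    """Monte-Carlo log predictive density of a patient's series.

    Parameters
    ----------
    hypothesis : 0 (control: flat means) or 1 (case: MRF change-point mixture)
    n_visits : score only the first ``n_visits`` visits (default: all)
    max_draws : cap on retained draws used (evenly thinned)
    n_rep : Monte Carlo replications of (log gamma, tau) per retained draw
    """
    if hypothesis not in (0, 1):
        raise ValueError("hypothesis must be 0 or 1")
    if samples.n_retained == 0:
        raise ValueError("empty posterior sample")
    marker_names = samples.marker_names
    t, Y = _series_arrays(series, marker_names)
    if n_visits is not None:
        t, Y = t[:n_visits], Y[:n_visits]
    T = t.size
    if T == 0:
        raise ValueError("series has no visits")
    d = float(t[-1])
    K = len(marker_names)

    idx = _thin_index(samples.n_retained, max_draws)
    mu_theta = samples.flat("mu_theta")[idx]
    sigma_theta2 = samples.flat("sigma_theta2")[idx]
    sigma2 = samples.flat("sigma2")[idx]
    S = idx.size

    # flat-model per-marker log density: (S, K)
    resid0 = Y.T[None, :, :] - mu_theta[:, :, None]
    logp0 = _rank_one_normal_logpdf(resid0, sigma2, sigma_theta2)
    if hypothesis == 0:
        return float(logsumexp(logp0.sum(axis=1)) - np.log(S))

    rng = np.random.default_rng(seed)
    mu_gamma = samples.flat("mu_gamma")[idx]
    sigma_gamma2 = samples.flat("sigma_gamma2")[idx]
    mu_I = samples.flat("mu_I")[idx]
    eta_I = samples.flat("eta_I")[idx]
    if n_rep > 1:
        reps = np.tile(np.arange(S), n_rep)
        mu_theta, sigma_theta2, sigma2 = (mu_theta[reps], sigma_theta2[reps],
                                          sigma2[reps])
        mu_gamma, sigma_gamma2 = mu_gamma[reps], sigma_gamma2[reps]
        mu_I, eta_I = mu_I[reps], eta_I[reps]
        logp0 = logp0[reps]
        S = S * n_rep

    # one MC draw of (gamma, tau) per draw and marker
    from ..simulate import sample_truncated_changepoint

    log_gamma = rng.normal(mu_gamma, np.sqrt(sigma_gamma2))
    tau = sample_truncated_changepoint(d, MU_TAU, SIGMA_TAU2, TAU_STAR, rng,
                                       size=(S, K))
    shift = np.exp(log_gamma)[:, :, None] * np.clip(
        t[None, None, :] - tau[:, :, None], 0.0, None
    )
    resid1 = Y.T[None, :, :] - mu_theta[:, :, None] - shift
    logp1 = _rank_one_normal_logpdf(resid1, sigma2, sigma_theta2)

    # exact mixture over the 2^K MRF states per draw
    states = enumerate_states(K)                        # (2^K, K)
    quad = np.einsum("sk,kl,sl->s", states, samples.R, states)
    state_logits = (mu_I[:, None] * states.sum(axis=1)[None, :]
                    + eta_I[:, None] * quad[None, :])   # (S, 2^K)
    state_logp = state_logits - logsumexp(state_logits, axis=1, keepdims=True)
    diff = logp1 - logp0                                # (S, K)
    per_draw = (logp0.sum(axis=1)[:, None] + state_logp
                + diff @ states.T)                      # (S, 2^K)
    log_pred = logsumexp(per_draw, axis=1)              # (S,)
    return float(logsumexp(log_pred) - np.log(S))


def bayes_risk(log_density_case: float, log_density_control: float,
               prevalence: float) -> float:
    """Posterior case probability from the two predictive log densities and
    the prevalence prior:  p * L1 / (p * L1 + (1-p) * L0)."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    from scipy.special import expit

    log_odds = (log_density_case - log_density_control
                + np.log(prevalence) - np.log1p(-prevalence))
    return float(expit(log_odds))


def risk_score(series: VisitSeries, samples: PosteriorSamples, prevalence,
               n_visits: int | None = None, seed: int = 0,
               max_draws: int | None = 2000, n_rep: int = 1) -> float:
    """P(case | series) by Bayes' rule on the two predictive densities."""
    prev = _as_prevalence(prevalence)
    t = series.ages if n_visits is None else series.ages[:n_visits]
    p = prev(float(t[-1]))
    lp1 = posterior_predictive_logdensity(series, samples, 1,
                                          n_visits=n_visits, seed=seed,
                                          max_draws=max_draws, n_rep=n_rep)
    lp0 = posterior_predictive_logdensity(series, samples, 0,
                                          n_visits=n_visits, seed=seed,
                                          max_draws=max_draws, n_rep=n_rep)
    return bayes_risk(lp1, lp0, p)


def risk_trajectory(series: VisitSeries, samples: PosteriorSamples, prevalence,
                    min_visits: int = 2, seed: int = 0,
                    max_draws: int | None = 2000) -> pd.DataFrame:
    """Per-visit risk from each prefix of at least ``min_visits`` visits."""
    rows = []
    for j in range(min_visits, series.n_visits + 1):
        rows.append({
            "patient_id": series.patient_id,
            "visit_index": j - 1,
            "age_years": float(series.ages[j - 1]),
            "risk": risk_score(series, samples, prevalence, n_visits=j,
                               seed=seed, max_draws=max_draws),
            "model": "bcp",
        })
    return pd.DataFrame(rows)


def score_cohort(cohort: Cohort, samples: PosteriorSamples, prevalence,
                 min_visits: int = 2, seed: int = 0,
                 max_draws: int | None = 2000) -> pd.DataFrame:
    """Risk trajectories for every patient (risks.csv schema)."""
    frames = [
        risk_trajectory(p, samples, prevalence, min_visits=min_visits,
                        seed=seed, max_draws=max_draws)
        for p in cohort.patients
    ]
    return pd.concat(frames, ignore_index=True)
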