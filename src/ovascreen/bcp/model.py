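"""Model/Results surface of the Bayesian change-point screening model.

``BayesianChangePointModel`` is built from a :class:`~ovascreen.cohort.Cohort`
and fixed :class:`Hyperparams`; ``fit`` runs the MCMC (Gibbs blocks for the
conjugate layers, Metropolis-Hastings for the MRF coupling, reversible jump
for the per-case change-point components) and returns a :class:`BCPResults`
carrying the posterior draws, convergence diagnostics, a summary table and
posterior-predictive risk scoring.

Paper-scale defaults: two chains of 40,000 iterations with 5,000 burn-in,
i.e. 70,000 retained draws; tests and small studies pass reduced sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..cohort import Cohort
from .diagnostics import gelman_rubin
from .gibbs import (
    gibbs_update_mu_gamma, gibbs_update_mu_theta, gibbs_update_sigma2,
    gibbs_update_sigma_gamma2, gibbs_update_sigma_theta2, gibbs_update_theta,
)
from .hyperparams import Hyperparams
from .likelihood import PreparedData, log_likelihood
from .moves import mh_update_coupling, refresh_active_marker, rj_update_marker
from .state import MCMCState

__all__ = ["MCMCConfig", "PosteriorSamples", "run_mcmc",
           "BayesianChangePointModel", "BCPResults"]

_SCALAR_PARAMS = ("mu_I", "eta_I")
_MARKER_PARAMS = ("mu_theta", "sigma_theta2", "mu_gamma", "sigma_gamma2", "sigma2")


@dataclass
class MCMCConfig:
    """Chain-length configuration (paper-scale defaults)."""

    n_iter: int = 40_000
    burn_in: int = 5_000
    n_chains: int = 2
    store_subject: bool = False      # keep full theta/log_gamma/tau traces
    adapt: bool = True               # tune MH step sizes during burn-in only
    check_every: int = 200           # log-likelihood finiteness check cadence

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")

    @property
    def n_kept_per_chain(self) -> int:
        return self.n_iter - self.burn_in

    @property
    def n_retained(self) -> int:
        """Total retained draws across chains (70,000 at the defaults)."""
        return self.n_chains * self.n_kept_per_chain


@dataclass
class PosteriorSamples:
    """Per-chain MCMC draws with burn-in bookkeeping.

    ``params`` maps parameter name -> array with leading axes
    (n_chains, n_kept); per-marker parameters add a trailing K axis and the
    indicator trace ``I`` has shape (n_chains, n_kept, n_cases, K).
    """

    params: dict
    n_iter: int
    burn_in: int
    n_chains: int
    seed: int
    marker_names: list
    R: np.ndarray
    acceptance: dict = field(default_factory=dict)
    subject_means: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.marker_names)

    @property
    def n_kept_per_chain(self) -> int:
        return self.n_iter - self.burn_in

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_kept_per_chain

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (n_retained, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_chain_matrix(self) -> dict:
        """Per-scalar-component chain matrices (for R-hat)."""
        out = {}
        for name in _SCALAR_PARAMS:
            out[name] = self.params[name]
        for name in _MARKER_PARAMS:
            for k, m in enumerate(self.marker_names):
                out[f"{name}[{m}]"] = self.params[name][:, :, k]
        return out

    def gelman_rubin(self) -> dict:
        return {k: gelman_rubin(v) for k, v in self.scalar_chain_matrix().items()}

    # -------------------------------------------------------------- persistence

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "samples.npz", R=self.R, **self.params)
        np.savez_compressed(directory / "subject_means.npz", **self.subject_means)
        manifest = {
            "n_iter": self.n_iter, "burn_in": self.burn_in,
            "n_chains": self.n_chains, "seed": self.seed,
            "marker_names": self.marker_names,
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with np.load(directory / "samples.npz") as z:
            arrays = {k: z[k] for k in z.files}
        R = arrays.pop("R")
        with np.load(directory / "subject_means.npz") as z:
            subject_means = {k: z[k] for k in z.files}
        return cls(params=arrays, R=R, subject_means=subject_means,
                   n_iter=manifest["n_iter"], burn_in=manifest["burn_in"],
                   n_chains=manifest["n_chains"], seed=manifest["seed"],
                   marker_names=manifest["marker_names"],
                   acceptance=manifest.get("acceptance", {}))


def _run_chain(prep: PreparedData, hyper: Hyperparams, config: MCMCConfig,
               rng) -> tuple[dict, dict, dict]:
    K, N, nc = prep.K, prep.N, prep.n_cases
    kept = config.n_kept_per_chain
    state = MCMCState.from_prior(prep, hyper, rng)

    store = {
        "mu_I": np.empty(kept), "eta_I": np.empty(kept),
        **{name: np.empty((kept, K)) for name in _MARKER_PARAMS},
        "I": np.empty((kept, nc, K), dtype=np.uint8),
    }
    if config.store_subject:
        store["theta"] = np.empty((kept, N, K))
        store["log_gamma"] = np.empty((kept, nc, K))
        store["tau"] = np.empty((kept, nc, K))
    run_sums = {"theta": np.zeros((N, K)), "I": np.zeros((nc, K))}

    step_mu, step_eta = 0.4, 0.8
    acc_mu = acc_eta = n_mh = 0

    for it in range(config.n_iter):
        for k in range(K):
            gibbs_update_theta(prep, k, state, hyper, rng)
            gibbs_update_mu_theta(prep, k, state, hyper, rng)
            gibbs_update_sigma_theta2(prep, k, state, hyper, rng)
            gibbs_update_mu_gamma(prep, k, state, hyper, rng)
            gibbs_update_sigma_gamma2(prep, k, state, hyper, rng)
            gibbs_update_sigma2(prep, k, state, hyper, rng)
        if nc:
            a_mu, a_eta = mh_update_coupling(state, hyper, rng,
                                             step_mu=step_mu, step_eta=step_eta)
            acc_mu += a_mu
            acc_eta += a_eta
            n_mh += 1
            if config.adapt and it < config.burn_in and (it + 1) % 50 == 0:
                # Robbins-Monro style tuning toward ~40% acceptance,
                # frozen at the end of burn-in to preserve ergodicity
                step_mu = float(np.clip(step_mu * np.exp(acc_mu / 50 - 0.4),
                                        1e-3, 10.0))
                step_eta = float(np.clip(step_eta * np.exp(acc_eta / 50 - 0.4),
                                         1e-3, 10.0))
                acc_mu = acc_eta = 0
                n_mh = 0
            for k in range(K):
                rj_update_marker(prep, k, state, hyper, rng)
                refresh_active_marker(prep, k, state, hyper, rng)

        if (it + 1) % config.check_every == 0:
            ll = log_likelihood(prep, state.theta, state.sigma2,
                                state.I, state.gamma, state.tau)
            if not np.isfinite(ll):
                raise RuntimeError(
                    f"non-finite log-likelihood at iteration {it + 1}; "
                    f"state summary: sigma2={state.sigma2}, "
                    f"mu_theta={state.mu_theta}, mu_I={state.mu_I}"
                )

        if it >= config.burn_in:
            s = it - config.burn_in
            store["mu_I"][s] = state.mu_I
            store["eta_I"][s] = state.eta_I
            for name in _MARKER_PARAMS:
                store[name][s] = getattr(state, name)
            store["I"][s] = state.I
            if config.store_subject:
                store["theta"][s] = state.theta
                store["log_gamma"][s] = state.log_gamma
                store["tau"][s] = state.tau
            run_sums["theta"] += state.theta
            run_sums["I"] += state.I

    subject_means = {name: arr / kept for name, arr in run_sums.items()}
    acceptance = {
        "mu_I": acc_mu / max(n_mh, 1),
        "eta_I": acc_eta / max(n_mh, 1),
    }
    return store, subject_means, acceptance


def run_mcmc(cohort: Cohort, hyper: Hyperparams | None = None,
             n_iter: int = 40_000, burn_in: int = 5_000, n_chains: int = 2,
             seed: int = 0, **config_kwargs) -> PosteriorSamples:
    """Run the full sampler and return pooled posterior draws.

    Chains are initialised independently from the priors; the retained
    sample count is ``n_chains * (n_iter - burn_in)``.
    """
    if cohort.n_cases < 1 or cohort.n_controls < 1:
        raise ValueError("cohort must contain at least one control and one case")
    prep = PreparedData.from_cohort(cohort)
    if hyper is None:
        hyper = Hyperparams.default(K=prep.K)
    if hyper.K != prep.K:
        raise ValueError("hyperparameter dimension must match the marker panel")
    config = MCMCConfig(n_iter=n_iter, burn_in=burn_in, n_chains=n_chains,
                        **config_kwargs)
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chain_stores, chain_means, chain_acc = [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        store, means, acc = _run_chain(prep, hyper, config, rng)
        chain_stores.append(store)
        chain_means.append(means)
        chain_acc.append(acc)
    params = {
        name: np.stack([cs[name] for cs in chain_stores])
        for name in chain_stores[0]
    }
    subject_means = {
        name: np.mean([cm[name] for cm in chain_means], axis=0)
        for name in chain_means[0]
    }
    acceptance = {
        name: float(np.mean([ca[name] for ca in chain_acc]))
        for name in chain_acc[0]
    }
    samples = PosteriorSamples(
        params=params, n_iter=n_iter, burn_in=burn_in, n_chains=n_chains,
        seed=seed, marker_names=list(cohort.biomarker_names), R=hyper.R,
        acceptance=acceptance, subject_means=subject_means,
    )
    assert samples.n_retained == config.n_retained
    return samples


class BayesianChangePointModel:
    """Joint multivariable Bayesian change-point screening model."""

    def __init__(self, cohort: Cohort, hyper: Hyperparams | None = None):
        self.cohort = cohort
        self.hyper = hyper if hyper is not None else Hyperparams.default(
            K=len(cohort.biomarker_names)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, markers=None,
                       hyper: Hyperparams | None = None):
        return cls(Cohort.from_frame(df, biomarker_names=markers), hyper=hyper)

    def fit(self, n_iter: int = 40_000, burn_in: int = 5_000, n_chains: int = 2,
            seed: int = 0, **config_kwargs) -> "BCPResults":
        samples = run_mcmc(self.cohort, self.hyper, n_iter=n_iter,
                           burn_in=burn_in, n_chains=n_chains, seed=seed,
                           **config_kwargs)
        return BCPResults(model=self, samples=samples)


class BCPResults:
    """Posterior draws plus diagnostics and predictive screening."""

    def __init__(self, model: BayesianChangePointModel | None,
                 samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    @property
    def marker_names(self):
        return self.samples.marker_names

    def gelman_rubin(self) -> dict:
        return self.samples.gelman_rubin()

    def converged(self, threshold: float = 1.1) -> bool:
        return max(self.gelman_rubin().values()) < threshold

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/90% interval and R-hat per population parameter."""
        rows = []
        rhat = self.gelman_rubin()
        for name, chains in self.samples.scalar_chain_matrix().items():
            flat = chains.reshape(-1)
            lo, hi = np.percentile(flat, [5.0, 95.0])
            rows.append({
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "hdi_5%": lo,
                "hdi_95%": hi,
                "r_hat": rhat[name],
            })
        return pd.DataFrame(rows).set_index("parameter")

    def indicator_frequency(self) -> pd.DataFrame:
        """Posterior mean of each case's change indicators."""
        freq = self.samples.flat("I").mean(axis=0)
        return pd.DataFrame(freq, columns=self.marker_names)

    # predictive scoring lives in .predictive to keep this module light
    def predict_risk(self, series, prevalence, seed: int = 0, **kwargs):
        from .predictive import risk_score
        return risk_score(series, self.samples, prevalence, seed=seed, **kwargs)

    def risk_trajectory(self, series, prevalence, seed: int = 0, **kwargs):
        from .predictive import risk_trajectory
        return risk_trajectory(series, self.samples, prevalence, seed=seed,
                               **kwargs)
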