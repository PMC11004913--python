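"""Fixed hyperparameters of the hierarchical change-point model.

Hierarchy (per biomarker k, transformed scale Y = log(Z+4)):

* baseline level       theta_ik ~ N(mu_theta_k, sigma_theta2_k)
* population mean      mu_theta_k ~ N(mu0_k, sigma02_k)
* baseline variance    sigma_theta2_k ~ InvGamma(a_theta_k, b_theta_k)
* log slope            log gamma_ik ~ N(mu_gamma_k, sigma_gamma2_k)
* population slope     mu_gamma_k ~ N(mu1_k, sigma12_k)
* slope variance       sigma_gamma2_k ~ InvGamma(a_gamma_k, b_gamma_k)
* noise variance       sigma2_k ~ InvGamma(a_sigma, b_sigma)
* change point         tau_ik ~ TruncNormal_(d_i - tau_star, d_i)(d_i - mu_tau, sigma_tau2)
* indicator fraction   logistic(mu_I) ~ Beta(p1, p2), matched to mean 0.85 / sd 0.05
* coupling             eta_I ~ Beta(p3, p4)

The indicator-fraction prior encodes that roughly 15% of ovarian-cancer
cases never show a rising marker trajectory.  The change-point prior places
the onset of the rise two years before the last screen with a five-year
maximum preclinical window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..mrf import default_coupling_matrix

__all__ = ["match_beta_moments", "Hyperparams"]

#: prior mean / sd of the fraction of cases exhibiting a change point
INDICATOR_PRIOR_MEAN = 0.85
INDICATOR_PRIOR_SD = 0.05

#: change-point prior: parent mean mu_tau years before the last screen,
#: parent variance sigma_tau2, truncation to the preclinical window tau_star
MU_TAU = 2.0
SIGMA_TAU2 = 0.75
TAU_STAR = 5.0


def match_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(p1, p2) shape parameters with the requested mean and sd.

    Uses nu = mean(1-mean)/sd^2 - 1, p1 = mean*nu, p2 = (1-mean)*nu.
    Raises ``ValueError`` when sd^2 >= mean(1-mean) (infeasible for a Beta).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie in (0, 1)")
    if sd <= 0 or sd * sd >= mean * (1.0 - mean):
        raise ValueError("need 0 < sd^2 < mean(1-mean)")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def _as_vec(x, K: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(K, float(arr))
    if arr.shape != (K,):
        raise ValueError(f"expected scalar or length-{K} vector, got shape {arr.shape}")
    return arr


@dataclass
class Hyperparams:
    """Deterministic hyperparameters for a K-marker panel.

    Per-marker entries accept scalars (broadcast to all markers) or
    length-K vectors.
    """

    K: int
    mu0: np.ndarray = 3.0            # prior mean of mu_theta_k
    sigma02: np.ndarray = 1.0        # prior variance of mu_theta_k
    a_theta: np.ndarray = 3.0        # IG shape, sigma_theta2_k
    b_theta: np.ndarray = 0.5        # IG scale, sigma_theta2_k
    mu1: np.ndarray = -0.3           # prior mean of mu_gamma_k (log-slope)
    sigma12: np.ndarray = 0.5        # prior variance of mu_gamma_k
    a_gamma: np.ndarray = 3.0        # IG shape, sigma_gamma2_k
    b_gamma: np.ndarray = 0.5        # IG scale, sigma_gamma2_k
    a_sigma: np.ndarray = 3.0        # IG shape, sigma2_k
    b_sigma: np.ndarray = 0.2        # IG scale, sigma2_k
    p1: float = None                 # Beta shape for logistic(mu_I)
    p2: float = None
    p3: float = 2.0                  # Beta shape for eta_I
    p4: float = 2.0
    mu_tau: float = MU_TAU
    sigma_tau2: float = SIGMA_TAU2
    tau_star: float = TAU_STAR
    R: np.ndarray = None             # strictly upper-triangular coupling

    def __post_init__(self):
        K = self.K
        for name in (
            "mu0", "sigma02", "a_theta", "b_theta",
            "mu1", "sigma12", "a_gamma", "b_gamma", "a_sigma", "b_sigma",
        ):
            setattr(self, name, _as_vec(getattr(self, name), K))
        for name in (
            "sigma02", "a_theta", "b_theta", "sigma12",
            "a_gamma", "b_gamma", "a_sigma", "b_sigma",
        ):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.p1 is None or self.p2 is None:
            self.p1, self.p2 = match_beta_moments(
                INDICATOR_PRIOR_MEAN, INDICATOR_PRIOR_SD
            )
        if min(self.p1, self.p2, self.p3, self.p4) <= 0:
            raise ValueError("Beta shapes must be positive")
        if self.sigma_tau2 <= 0 or self.tau_star <= 0:
            raise ValueError("sigma_tau2 and tau_star must be positive")
        if self.R is None:
            self.R = default_coupling_matrix(K)
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (K, K):
            raise ValueError("R must be K x K")

    @classmethod
    def default(cls, K: int = 3, **overrides) -> "Hyperparams":
        """Default panel-agnostic priors (weakly informative on log scale)."""
        return cls(K=K, **overrides)
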