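"""Independent oracles shared by the unit and acceptance suites.

Everything here is deliberately brute force — grid evaluation, explicit pair
counting, exhaustive enumeration, quadrature — and never calls the code path
it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def ks_distance_to_grid(draws, grid, log_density) -> float:
    """Kolmogorov-Smirnov distance between sampled draws and the
    distribution given by unnormalised log density values on a grid."""
    dens = np.exp(log_density - log_density.max())
    # trapezoid-weighted CDF on the grid
    dx = np.diff(grid)
    mass = 0.5 * (dens[1:] + dens[:-1]) * dx
    cdf = np.concatenate([[0.0], np.cumsum(mass)])
    cdf /= cdf[-1]
    draws = np.sort(draws)
    F_grid = np.interp(draws, grid, cdf)
    n = draws.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(emp_hi - F_grid)),
                     np.max(np.abs(F_grid - emp_lo))))


def auc_pair_counting(labels, scores) -> float:
    """AUC by explicit enumeration of all case-control pairs (ties = 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    wins = ties = 0
    for c in case:
        for u in ctrl:
            if c > u:
                wins += 1
            elif c == u:
                ties += 1
    return (wins + 0.5 * ties) / (case.size * ctrl.size)


def sens_at_spec_scan(labels, scores, specificity=0.90):
    """Sensitivity/threshold by scanning every candidate cutoff."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    ctrl = scores[labels == 0]
    case = scores[labels == 1]
    best = None
    for th in sorted(set(scores)) + [max(scores) + 1.0]:
        spec = np.mean(ctrl < th)
        if spec >= specificity:
            best = th
            break
    return float(np.mean(case >= best)), float(best)


def exact_sign_flip_p(d) -> float:
    """Exact one-sided sign-flip p-value by full enumeration."""
    d = np.asarray(d, dtype=float)
    n = d.size
    obs = d.mean()
    count = 0
    for i in range(2**n):
        signs = np.array([1.0 if (i >> j) & 1 else -1.0 for j in range(n)])
        if (signs * d).mean() >= obs - 1e-12:
            count += 1
    return count / 2**n


def case_marginal_likelihood_1marker(y, t, theta, sigma2, mu_gamma,
                                     sigma_gamma2, d, mu_tau, sigma_tau2,
                                     tau_star, n_quad=80):
    """∫∫ N(y; theta + e^g (t-tau)+, sigma2) p(g) p(tau) dg dtau by
    tensorised Gauss-Legendre quadrature (log-slope g, change point tau)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    sd_g = np.sqrt(sigma_gamma2)
    g_lo, g_hi = mu_gamma - 8 * sd_g, mu_gamma + 8 * sd_g
    tau_lo, tau_hi = d - tau_star, d

    gx, gw = np.polynomial.legendre.leggauss(n_quad)
    g_nodes = 0.5 * (g_hi - g_lo) * gx + 0.5 * (g_hi + g_lo)
    g_weights = 0.5 * (g_hi - g_lo) * gw
    tau_nodes = 0.5 * (tau_hi - tau_lo) * gx + 0.5 * (tau_hi + tau_lo)
    tau_weights = 0.5 * (tau_hi - tau_lo) * gw

    sd_tau = np.sqrt(sigma_tau2)
    tau_prior = norm.pdf(tau_nodes, loc=d - mu_tau, scale=sd_tau)
    tau_prior /= (norm.cdf(tau_hi, loc=d - mu_tau, scale=sd_tau)
                  - norm.cdf(tau_lo, loc=d - mu_tau, scale=sd_tau))
    g_prior = norm.pdf(g_nodes, loc=mu_gamma, scale=sd_g)

    # tensorised over (g, tau) nodes: mean has shape (n_g, n_tau, T)
    gamma = np.exp(g_nodes)[:, None, None]
    pos = np.clip(t[None, None, :] - tau_nodes[None, :, None], 0.0, None)
    mean = theta + gamma * pos
    log_lik = norm.logpdf(y[None, None, :], loc=mean,
                          scale=np.sqrt(sigma2)).sum(axis=2)
    weights = ((g_prior * g_weights)[:, None]
               * (tau_prior * tau_weights)[None, :])
    return float(np.sum(np.exp(log_lik) * weights))


def flat_marginal_likelihood_1marker(y, theta, sigma2):
    y = np.asarray(y, dtype=float)
    return float(np.prod(norm.pdf(y, loc=theta, scale=np.sqrt(sigma2))))
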