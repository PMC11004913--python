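import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ovascreen import PosteriorSamples, PrevalencePrior, VisitSeries
from ovascreen.bcp.hyperparams import MU_TAU, SIGMA_TAU2, TAU_STAR
from ovascreen.bcp.predictive import (bayes_risk,
                                      posterior_predictive_logdensity,
                                      risk_score, risk_trajectory)
from ovascreen.mrf import default_coupling_matrix

from helpers import (case_marginal_likelihood_1marker,
                     flat_marginal_likelihood_1marker)


def _frozen_samples(K=1, n=1, mu_theta=2.8, sigma_theta2=0.15, mu_gamma=-0.1,
                    sigma_gamma2=0.2, sigma2=0.05, mu_I=1.2, eta_I=0.3):
    """PosteriorSamples holding ``n`` copies of one population draw."""
    def tile(val):
        return np.broadcast_to(np.asarray(val, dtype=float),
                               (1, n, K)).copy()

    params = {
        "mu_theta": tile(mu_theta), "sigma_theta2": tile(sigma_theta2),
        "mu_gamma": tile(mu_gamma), "sigma_gamma2": tile(sigma_gamma2),
        "sigma2": tile(sigma2),
        "mu_I": np.full((1, n), mu_I), "eta_I": np.full((1, n), eta_I),
        "I": np.zeros((1, n, 0, K), dtype=np.uint8),
    }
    names = ["m%d" % k for k in range(K)]
    return PosteriorSamples(params=params, n_iter=n, burn_in=0, n_chains=1,
                            seed=0, marker_names=names,
                            R=default_coupling_matrix(K))


def _series(raw_levels, ages=(58.0, 60.0, 62.0), K=1, status=0):
    levels = {f"m{k}": list(raw_levels) for k in range(K)}
    return VisitSeries("x", status, ages=list(ages)[:len(raw_levels)],
                       levels=levels,
                       diagnosis_age=ages[len(raw_levels) - 1] if status else None)


class TestBayesRisk:
    def test_equal_densities_return_prevalence(self):
        for p in (0.01, 0.2, 0.7):
            assert bayes_risk(np.log(0.3), np.log(0.3), p) == pytest.approx(p)

    def test_arithmetic_example(self):
        """densities (case 0.6, control 0.2), prevalence 0.01 -> 0.0294117."""
        risk = bayes_risk(np.log(0.6), np.log(0.2), 0.01)
        assert risk == pytest.approx(0.6 * 0.01 / (0.2 * 0.99 + 0.6 * 0.01),
                                     abs=1e-12)

    def test_overwhelming_likelihood_ratio_saturates(self):
        assert bayes_risk(0.0, -1e6, 0.01) == pytest.approx(1.0)
        assert bayes_risk(-1e6, 0.0, 0.5) == pytest.approx(0.0)

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            bayes_risk(0.0, 0.0, 0.0)


def test_flat_series_favours_control_hypothesis():
    samples = _frozen_samples()
    flat = _series([12.0, 11.0, 12.5])
    lp0 = posterior_predictive_logdensity(flat, samples, 0)
    lp1 = posterior_predictive_logdensity(flat, samples, 1, seed=1)
    assert lp0 > lp1


def test_rising_series_favours_case_hypothesis():
    samples = _frozen_samples()
    rising = _series([12.0, 40.0, 200.0])
    lp0 = posterior_predictive_logdensity(rising, samples, 0)
    lp1 = posterior_predictive_logdensity(rising, samples, 1, seed=1,
                                          n_rep=50)
    assert lp1 > lp0


def test_case_density_matches_quadrature_oracle():
    """Frozen population parameters, one marker, two visits: the MC
    predictive density agrees with (theta, I, gamma, tau) numerical
    integration to ~2 decimal places in log units."""
    pars = dict(mu_theta=2.8, sigma_theta2=0.15, mu_gamma=-0.1,
                sigma_gamma2=0.2, sigma2=0.05, mu_I=1.2)
    samples = _frozen_samples(n=2000, **pars)
    series = _series([14.0, 45.0], ages=(60.0, 62.0))
    lp1 = posterior_predictive_logdensity(series, samples, 1, seed=3,
                                          max_draws=None, n_rep=200)
    # oracle: integrate theta on a grid; (gamma, tau) by Gauss-Legendre
    y = np.log(np.array([14.0, 45.0]) + 4.0)
    t = np.array([60.0, 62.0])
    thetas = np.linspace(pars["mu_theta"] - 6 * np.sqrt(pars["sigma_theta2"]),
                         pars["mu_theta"] + 6 * np.sqrt(pars["sigma_theta2"]),
                         241)
    w_theta = np.exp(-0.5 * (thetas - pars["mu_theta"]) ** 2
                     / pars["sigma_theta2"])
    w_theta /= w_theta.sum()
    p_change = expit(pars["mu_I"])
    acc = 0.0
    for th, w in zip(thetas, w_theta):
        L0 = flat_marginal_likelihood_1marker(y, th, pars["sigma2"])
        L1 = case_marginal_likelihood_1marker(
            y, t, th, pars["sigma2"], pars["mu_gamma"], pars["sigma_gamma2"],
            d=62.0, mu_tau=MU_TAU, sigma_tau2=SIGMA_TAU2, tau_star=TAU_STAR,
            n_quad=100)
        acc += w * ((1 - p_change) * L0 + p_change * L1)
    assert lp1 == pytest.approx(np.log(acc), abs=0.02)


def test_control_density_exact_against_theta_grid():
    pars = dict(mu_theta=2.8, sigma_theta2=0.15, sigma2=0.05)
    samples = _frozen_samples(**pars)
    series = _series([14.0, 45.0], ages=(60.0, 62.0))
    lp0 = posterior_predictive_logdensity(series, samples, 0)
    y = np.log(np.array([14.0, 45.0]) + 4.0)
    thetas = np.linspace(1.0, 5.0, 30_001)
    w = np.exp(-0.5 * (thetas - pars["mu_theta"]) ** 2 / pars["sigma_theta2"])
    w /= (w.sum() * (thetas[1] - thetas[0])) / (thetas[1] - thetas[0])
    w /= w.sum()
    lik = np.array([flat_marginal_likelihood_1marker(y, th, pars["sigma2"])
                    for th in thetas])
    assert lp0 == pytest.approx(np.log((w * lik).sum()), abs=1e-3)


def test_risk_invariant_to_marker_relabelling():
    """Permuting the marker panel (and the per-marker parameter axes)
    leaves the risk unchanged up to Monte Carlo noise."""
    mu_theta = [2.5, 3.8]
    sigma2 = [0.05, 0.08]
    samples = _frozen_samples(K=2, n=500, mu_theta=mu_theta, sigma2=sigma2)
    ages = (58.0, 60.0, 62.0)
    levels = {"m0": [11.0, 30.0, 90.0], "m1": [40.0, 42.0, 160.0]}
    series = VisitSeries("x", 0, ages=list(ages), levels=levels)

    perm_samples = _frozen_samples(K=2, n=500, mu_theta=mu_theta[::-1],
                                   sigma2=sigma2[::-1])
    perm_samples.marker_names = ["m1", "m0"]

    r1 = risk_score(series, samples, 0.1, seed=5, n_rep=100, max_draws=None)
    r2 = risk_score(series, perm_samples, 0.1, seed=6, n_rep=100,
                    max_draws=None)
    assert r1 == pytest.approx(r2, abs=0.02)


def test_trajectory_schema_and_bounds():
    samples = _frozen_samples()
    series = _series([12.0, 20.0, 80.0], status=1)
    traj = risk_trajectory(series, samples, PrevalencePrior.from_scalar(0.1))
    assert list(traj.visit_index) == [1, 2]
    assert traj.risk.between(0, 1).all()
    assert (traj.model == "bcp").all()
    # risks rise as the trajectory rises
    assert traj.risk.iloc[-1] >= traj.risk.iloc[0]


def test_empty_samples_rejected():
    samples = _frozen_samples(n=1)
    samples.params = {k: v[:, :0] for k, v in samples.params.items()}
    samples.n_iter = 0
    with pytest.raises(ValueError):
        posterior_predictive_logdensity(_series([10.0, 11.0]), samples, 0)


def test_prevalence_table_lookup():
    table = pd.DataFrame({"age_lo": [50, 55], "age_hi": [55, 60],
                          "prevalence": [0.001, 0.002]})
    prev = PrevalencePrior.from_age_bands(table, fallback=0.005)
    assert prev(52.0) == 0.001
    assert prev(57.0) == 0.002
    assert prev(70.0) == 0.005
    assert prev() == 0.005
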