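# ovascreen

Longitudinal multimarker screening models for early ovarian-cancer
detection.

Ovarian cancer is usually diagnosed late, when survival is poor. Serial
serum biomarkers — CA125 foremost, with HE4 and glycodelin (PAEP) as
complementary candidates — begin rising one to three years before clinical
diagnosis, so classifying a woman's *trajectory* rather than a single value
can buy lead time. `ovascreen` is for biostatisticians and screening
methodologists who want to fit, compare and stress-test two families of
longitudinal multimarker classifiers on such data (or on synthetic cohorts
when trial data are unavailable):

* **BCP** — a joint multivariable fully Bayesian change-point model. On the
  transformed scale `Y = log(Z + 4)`, controls fluctuate about a
  subject-specific baseline, `Y_ijk = θ_ik + ε_ijk`; for cases a latent
  indicator `I_ik` switches marker k to a change-point trajectory
  `Y_ijk = θ_ik + γ_ik (t_ij − τ_ik)_+ + ε_ijk`, with the indicators of one
  patient coupled across markers by a Markov random field
  `P(I_i) ∝ exp(μ_I Σ_k I_ik + η_I I_iᵀ R I_i)`. The full hierarchy is
  fitted by MCMC (conjugate Gibbs blocks, Metropolis–Hastings for the MRF
  coupling with an exactly enumerated normalising constant, and a
  reversible-jump birth/death move for `{I_ik, γ_ik, τ_ik}`), and new
  patients are scored through the posterior predictive combined with a
  prevalence prior via Bayes' rule.
* **RNN** — one scalar-input LSTM per biomarker plus one for screening age,
  last hidden states concatenated, dropout, and a sigmoid head; trained
  with Adam on cross-entropy (self-contained NumPy with exact
  backpropagation through time).

Around the two models: a synthetic-cohort generator drawn from the same
change-point law (with every latent recorded for recovery testing), and a
repeated stratified cross-validation evaluation layer — ROC/AUC,
sensitivity at 90% specificity, paired sign-flip permutation tests,
screening horizons (all history / 1 / 2 years before diagnosis), lead-time
statistics and diagnosed/missed contingency tables — over the scenario
matrix `m(1,2,3), m(1,2), m(1,3), u(1), u(2), u(3)` (markers numbered
CA125 = 1, HE4 = 2, glycodelin = 3).

See `docs/methods.md` for the model details, priors, sampler design and
known limitations.

## Worked example

```python
from ovascreen import (GeneratorConfig, generate_cohort,
                       BayesianChangePointModel, LSTMClassifier, LSTMConfig,
                       PrevalencePrior, auc, sensitivity_at_specificity)

cohort, truth = generate_cohort(GeneratorConfig(n_controls=60, n_cases=30, seed=1))
train = cohort.subset_patients(cohort.ids[::2])
test  = cohort.subset_patients(cohort.ids[1::2])

bcp = BayesianChangePointModel(train.subset_markers(["CA125", "HE4"]))
fit = bcp.fit(n_iter=1500, burn_in=500, n_chains=2, seed=0)
print(fit.summary().loc[["mu_I", "eta_I", "mu_theta[CA125]", "sigma2[CA125]"]].round(3))
print("max R-hat:", round(max(fit.gelman_rubin().values()), 3))

prev = PrevalencePrior.from_scalar(train.n_cases / train.n_patients)
risks = [fit.predict_risk(p, prev, max_draws=300)
         for p in test.subset_markers(["CA125", "HE4"]).patients]
labels = test.labels
print("BCP  m(1,2)  AUC %.3f  sens@90%%spec %.3f" % (
    auc(labels, risks), sensitivity_at_specificity(labels, risks)[0]))

res = LSTMClassifier(train, markers=["CA125", "HE4"],
                     config=LSTMConfig(hidden=8, dropout=0.2, epochs=100,
                                       learning_rate=0.01)).fit(seed=0)
risks = [res.predict_proba(p) for p in test.patients]
print("RNN  m(1,2)  AUC %.3f  sens@90%%spec %.3f" % (
    auc(labels, risks), sensitivity_at_specificity(labels, risks)[0]))
```

Output:

```
                  mean     sd  hdi_5%  hdi_95%  r_hat
parameter
mu_I             1.818  0.374   1.266    2.417  1.000
eta_I            0.500  0.220   0.137    0.844  1.001
mu_theta[CA125]  2.711  0.064   2.607    2.815  1.000
sigma2[CA125]    0.046  0.005   0.038    0.055  1.000
max R-hat: 1.034
BCP  m(1,2)  AUC 0.989  sens@90%spec 0.933
RNN  m(1,2)  AUC 0.976  sens@90%spec 0.933
```

Reading the numbers: the posterior mean of `logistic(mu_I)` near 0.85
recovers the generator's fraction of cases with a rising marker; `eta_I`
around 0.5 reflects the positive cross-marker coupling; `mu_theta[CA125]`
≈ 2.7 is the population CA125 baseline on the log(Z+4) scale (raw level
`exp(2.71) − 4 ≈ 11 U/mL`). R-hat below 1.1 indicates the two chains mixed.
On held-out patients the CA125–HE4 panel separates cases from controls
almost perfectly on this synthetic cohort (AUC ≈ 0.98–0.99), detecting
~93% of cases at the threshold that keeps 90% of controls below it.

## Command line

```bash
ovascreen simulate --seed 1 --out sim/
ovascreen bcp-fit  --cohort sim/cohort.csv --iters 2000 --burn-in 500 --seed 0 --out fit/
ovascreen bcp-score --samples fit/ --cohort sim/cohort.csv --prevalence 0.02 --out risks.csv
ovascreen rnn-fit  --cohort sim/cohort.csv --markers 1,2 --seed 0 --out model/
ovascreen rnn-score --model model/ --cohort sim/cohort.csv --out risks_rnn.csv
ovascreen evaluate --risks risks.csv --risks risks_rnn.csv --cohort sim/cohort.csv \
                   --horizons all,1,2 --out report/
ovascreen run --config experiment.yaml      # full simulate→fold→fit→score→evaluate
```

`run` takes a YAML config with keys `seed`, `generator` (or `cohort_csv`),
`scenarios`, `methods`, `horizons`, `cv`, `bcp`, `rnn`, `prevalence` and
`contingency_pairs`; every setting used is echoed to the run manifest.

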