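# Methods

`ovascreen` implements two longitudinal multimarker classifiers for early
ovarian-cancer screening — a joint multivariable Bayesian change-point model
(BCP) and a per-marker LSTM classifier (RNN) — together with a synthetic
cohort generator drawn from the same generative law and a cross-validated
evaluation layer. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic experiments do and do not show.

## Data model and preprocessing

A cohort holds 2–5 roughly annual screening visits per woman, each with raw
serum levels of up to three biomarkers (CA125, HE4, glycodelin/PAEP) and a
case/control label; cases carry an age at clinical diagnosis. All modelling
is done on the transformed scale `Y = log(Z + 4)`, whose shift keeps the
logarithm defined for small assay readouts; the inverse `exp(Y) − 4` is used
when emitting raw levels.

## The Bayesian change-point model

For controls, marker `k` of subject `i` fluctuates about a subject-specific
baseline: `Y_ijk = θ_ik + ε_ijk`, `ε ~ N(0, σ_k²)`. For cases, a latent
binary indicator `I_ik` selects between the same flat trajectory and a
change-point trajectory

    Y_ijk = θ_ik + γ_ik (t_ij − τ_ik)_+ + ε_ijk,

a linear post-onset rise (on the log scale) with subject-specific slope
`γ_ik > 0` starting at the latent change-point age `τ_ik`.

Hierarchy (all hyperparameters deterministic, per marker unless noted):

| layer | law | default |
|---|---|---|
| baseline | `θ_ik ~ N(μ_θk, σ_θk²)` | — |
| baseline mean | `μ_θk ~ N(μ_0k, σ_0k²)` | `N(3, 1)` |
| baseline variance | `σ_θk² ~ IG(a_θ, b_θ)` | `IG(3, 0.5)` |
| log slope | `log γ_ik ~ N(μ_γk, σ_γk²)` | — |
| slope mean | `μ_γk ~ N(μ_1k, σ_1k²)` | `N(−0.3, 0.5)` |
| slope variance | `σ_γk² ~ IG(a_γ, b_γ)` | `IG(3, 0.5)` |
| noise variance | `σ_k² ~ IG(a, b)` | `IG(3, 0.2)` |
| change point | `τ_ik ~ TN_(d_i−τ*, d_i)(d_i − μ_τ, σ_τ²)` | `μ_τ = 2` y, `σ_τ² = 0.75`, `τ* = 5` y |
| indicators | `I_i ~ MRF(μ_I, η_I; R)` | see below |

The indicators of one patient form a Markov random field
`P(I_i) ∝ exp(μ_I Σ_k I_ik + η_I I_iᵀ R I_i)` with `R` strictly upper
triangular (default: all ones, i.e. every marker pair coupled equally;
configurable). The conditional of one indicator given the rest is logistic
in the field `μ_I + η_I Σ_{k'≠k} S[k,k'] I_ik'` with `S = R + Rᵀ`, so a
change in one marker raises the odds of changes in the others whenever
`η_I > 0`. Priors: `logistic(μ_I) ~ Beta(p1, p2)` with `(p1, p2)` moment-
matched to mean 0.85 / sd 0.05 — giving `(42.5, 7.5)` — encoding that about
15% of cases never show a marker rise; `η_I ~ Beta(2, 2)` (a mild symmetric
prior on [0, 1]; the literature this model family follows does not pin the
shape down, so it is configurable). `μ_I` and `η_I` are shared across the K
markers of a patient, as the joint MRF form requires.

### Sampler

One sweep updates, in order:

1. **Conjugate Gibbs blocks.** `θ_ik` (normal–normal, with the change-point
   shift subtracted from case residuals), `μ_θk`, `σ_θk²`, `μ_γk`, `σ_γk²`
   (over active slopes only; the conditional reduces to the prior when no
   indicator is on) and `σ_k²`. Each full conditional is derived in the
   code (`bcp/gibbs.py`) and verified against grid-normalised
   prior × likelihood densities in the test suite.
2. **Metropolis–Hastings for (μ_I, η_I).** Random walks on `μ_I` and
   `logit(η_I)`; the target uses the exact MRF normalising constant by
   `2^K` state enumeration (panels up to K = 12), so the acceptance ratio
   is exact. Step sizes adapt toward ~40% acceptance during burn-in only
   and are frozen afterwards, preserving ergodicity.
3. **Reversible jump per case × marker.** A birth move proposes
   `(log γ, τ)` from their priors, making the proposal density cancel the
   prior so the acceptance ratio is the data likelihood ratio times the
   MRF conditional odds (Jacobian 1); the death move is the exact reverse.
   Because the trans-dimensional move alone would refresh `(γ, τ)` only at
   accepted births, active components also get within-model random-walk
   updates of `log γ` and `τ` (τ proposals outside the preclinical window
   `(d_i − τ*, d_i)` are rejected outright). Truncated-normal draws use
   inverse-CDF sampling of the parent normal, which is exact and fast.

Chains start from independent prior draws. Paper-scale defaults are two
chains of 40,000 iterations with 5,000 burn-in (70,000 retained draws);
tests and the bundled experiments use reduced sizes (hundreds to a few
thousand iterations on cohorts of 40–80 patients), which the recovery tests
show are sufficient for the population-level parameters at those cohort
sizes. Convergence is monitored by the classic between/within-chain
Gelman–Rubin factor with a configurable 1.1 threshold, and a periodic
log-likelihood finiteness check aborts a diverging run with a state dump.

### Screening

A new patient's series is scored by Bayes' rule on two posterior-predictive
densities. Conditional on one retained population draw, the subject baseline
is integrated out analytically: the T visits of marker k are jointly normal
with rank-one-plus-diagonal covariance `σ_k² I + σ_θk² 11ᵀ`, evaluated in
closed form. Under the case hypothesis the indicator configuration is mixed
*exactly* over the `2^K` MRF states per draw (Rao-Blackwellised), while one
Monte Carlo draw of `(log γ, τ)` per retained draw integrates the slope and
change point; the change-point window is anchored at the patient's current
last visit. Averages over retained draws use log-sum-exp; draws may be
thinned (`max_draws`) for speed. The prevalence prior is supplied by the
user — a scalar or an age-band table; no incidence figures are baked in —
and the pipeline defaults to the training-cohort case fraction, which
rescales risks monotonically and therefore leaves rank-based metrics (AUC,
sensitivity at fixed specificity) unchanged.

## The LSTM classifier

Each selected biomarker feeds its own scalar-input LSTM, and the screening
age is always included as an additional channel. Gates follow the standard
formulation (sigmoid input/forget/output gates, tanh candidate); the last
hidden states of all channels are concatenated, dropout is applied to the
concatenated vector at training time only, and a sigmoid head produces the
risk. Training minimises mean binary cross-entropy by full-batch gradient
descent with Adam (fixed learning rate 1e-3 and 100 epochs by default —
meta-parameters, not tuned), with Glorot-uniform input weights, random
orthogonal recurrent kernels, and zero biases. The implementation is
self-contained NumPy with hand-derived backpropagation through time;
gradients are exact and are verified against central finite differences.

Inputs are standardised per channel (mean/sd pooled over the training
split's visits) and the same transformation is applied at evaluation;
variable-length sequences are handled natively, and a padded+masked forward
path is provided and tested to be exactly inert on masked steps. Patients
with fewer than two visits are skipped with a warning. Hyperparameter
tuning searches hidden size × dropout (default grid {4, 8, 16} × {0.0, 0.2,
0.4}) by repeated stratified inner cross-validation (10-fold × 3 by
default), selecting the highest mean validation AUC with ties broken toward
the smaller network and lower dropout. AUC is the package's inner selection
metric by default (configurable); hidden sizes are shared across channels
unless overridden for the age channel.

## Synthetic cohorts

The generator draws cohorts from exactly the change-point law above:
control trajectories are flat noise about `θ_ik`; cases draw an indicator
vector from the MRF, and active markers get a truncated-normal change point
(mode two years before the last screen, five-year window) and a log-normal
slope. Defaults emulate the screening study design the models target:
180 controls / 44 cases; cases with 2/3/5 annual visits in proportion
10:10:24 and controls with 4–5 (2:178); entry ages uniform on [52, 72];
three markers with baselines 2.8 / 4.0 / 3.5 on the transformed scale
(between-subject sd ≈ 0.35, noise sd 0.2), mean log slope −0.3 (median rise
≈ 0.74 log units/year after onset), and MRF coupling `η_I = 0.3`. The field
`μ_I` is calibrated by exact enumeration so the marginal per-marker change
probability equals 0.85 despite the coupling (with `η_I = 0` it reduces to
`logit(0.85)` exactly). Diagnosis age defaults to the last screen (gap
configurable). Raw levels are emitted as `exp(Y) − 4` and floored just
above −4 (with a warning) so the pipeline's own transform round-trips.

What the generator does **not** emulate: assay batch effects, visit
dropout, age-dependent baselines, non-Gaussian noise, or multiple/nonlinear
change shapes. Passing tests therefore demonstrate correctness of the
machinery and recovery under the model's own assumptions — not performance
on real trial data, whose headline numbers are not reproducible without the
original assays.

## Evaluation layer

Outer evaluation is repeated stratified k-fold cross-validation (5 × 2 by
default). Per fold and scenario (marker subsets tagged `m(1,2,3)`,
`m(1,2)`, `m(1,3)`, `u(1)`, `u(2)`, `u(3)` in panel order CA125, HE4,
glycodelin), risks are computed for every visit prefix of ≥ 2 visits, and:

* **AUC** uses the Mann–Whitney normalisation with half-weight ties
  (verified against explicit pair counting).
* **Sensitivity at 90% specificity** takes the smallest cutoff keeping 90%
  of the fold's *test* controls below it (train-side thresholds are a
  configurable alternative; the choice is a declared convention), scoring
  threshold ties as abnormal.
* **Screening horizons**: `all` evaluates each patient's last visit; an
  h-year horizon evaluates the last visit at least h years before
  diagnosis, with controls truncated by the same calendar span before
  their last visit (controls have no diagnosis date, so this mirrored
  truncation is a declared convention).
* **Lead time** is diagnosis age minus the age at the earliest visit whose
  risk reaches the fold's 90%-specificity threshold; undetected cases are
  excluded and reported via the contingency table of diagnosed/missed
  cases pooled over folds.
* **Uncertainty**: across-fold means with normal-approximation 95% CIs
  (mean ± 1.96 SE) by default; a bootstrap option is provided.
* **Model comparison**: one-sided sign-flip permutation test on the paired
  per-fold differences, with exact enumeration of all 2^n sign patterns
  when feasible (2^10 = 1024 at the default ten folds) and 10,000 random
  flips otherwise.

## Reproducibility and numerics

All randomness flows from explicit integer seeds; the pipeline derives
per-stage seeds (< 2^31) from one global seed via SHA-256 so stages are
independently reproducible, and a run manifest echoes every setting.
Degenerate inputs are handled by construction: empty conditioning sets fall
back to priors, risks at exactly 0/1 are clipped at 1e-7 with a warning,
one-class training sets are rejected, and zero-variance channels scale by 1.

## Known limitations

* The MRF enumeration limits panels to 12 markers (three are used here).
* Reversible-jump mixing degrades if the slope prior is far from the data's
  scale; the within-model refreshment mitigates but does not remove this.
* The LSTM trains full-batch on CPU; it is sized for screening cohorts of
  hundreds of patients, not for large-scale deep learning.
* Lead-time summaries condition on detection, so models that detect fewer,
  easier cases can show optimistic lead times; read them together with the
  contingency table.
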