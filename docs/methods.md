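# Methods

## Models

**Lagged logistic choice model.**  Choices are binary, `a_t ∈ {0, 1}`.  The
model assumes `Pr(a_t = 1) = σ(ΔQ_t)` with `σ` the logistic function and

    ΔQ_t = β₀ + Σ_{k=1..L} β_k s_{t−k},    s = 2a − 1 ∈ {−1, +1}.

The signed coding is fixed package-wide so that β₁ < 0 always means a
propensity to alternate and β₁ > 0 inertia; flipping every bit of a sequence
negates the design and flips the responses (a tested symmetry).  Trials are
1-based in files and 0-based in memory; the first `L` trials of a sequence
are dropped from the likelihood rather than padded — imputing history would
fabricate data, and the model is explicitly conditional on `L` real
preceding trials.

Conditional on the regressors, trials are independent Bernoulli draws, so
ordinary maximum likelihood is valid even though the sequence feeds back
into its own design.  That feedback is not innocuous for *finite-sample
bias*, though: see Limitations.

**Reward-augmented model (operant learning).**  For two-armed-bandit data
the linear predictor becomes
`ΔQ_t = β₀ + Σ_k s_{t−k}(α_k r_{t−k} + β_k)`.  The interaction weights α_k
act as learned action values — under `α_k = γ^k/T`, `β = 0`, the rule is
softmax temporal-difference learning with discount γ and temperature T —
while β_k are the residual, reward-independent sequential effects.  α and β
are estimated jointly in one fit (the predictor is a single linear form;
staged estimation would bias both parts).  Blocks are separate sequences:
histories never cross block boundaries, and a participant's blocks enter one
fit as stacked designs.

## Estimation

`fit_logistic_mle` is a Newton/IRLS maximizer of the weighted Bernoulli
log-likelihood with score tolerance 1e−8 and at most 100 iterations,
step-halved so the (penalized) log-likelihood never decreases.  Standard
errors come from the inverse observed information; Wald p-values use the
normal approximation.  Confidence intervals are reported at whatever level
the caller passes — analyses that test `L` lags pass the Bonferroni level
`α/m` (`bonferroni_level`).  Two deliberate non-defaults:

* **Separation** does not raise: coefficients are capped at |β| = 20 and the
  fit flagged `converged=False`, so cross-validation can still consume its
  (saturated) predictions.
* **Ridge** (L2) exists only for the discounted stationarity refits, where
  an effective sample size near 1 cannot identify L+1 parameters; it is
  1e−4 there and 0 everywhere else.

The fitter is validated two independent ways: against statsmodels'
GLM(Binomial) on the same designs (agreement to 1e−6) and against a
brute-force grid search of the exact likelihood on small L = 1 instances
(agreement to the 0.01 grid resolution).

Hard calls break the `p = 0.5` tie deterministically toward symbol 1:
reproducibility beats an unseedable coin flip, and ties have measure zero
under continuous estimates.

## Synthetic data

The generators define the conditions under which everything is tested; no
human data ship with the package.

* **Fair coins** are the chance reference everywhere.
* **Logistic agents** run the choice model generatively.  The first `L`
  choices are fair draws (the model is silent about initial history; a
  fair-coin warm-up washes out within a few trials and imposes nothing).
  Populations draw per-participant coefficient vectors componentwise from
  Normal(beta_mean, beta_sd) and return the truth table for recovery tests.
  The canonical heterogeneous population used in the tests is 30
  participants × 1,000 trials with β₁ ~ N(0, 1) and a common β₃ = −0.4 —
  a mean-zero idiosyncratic short-lag effect on top of a shared
  alternation-at-lag-3 bias, sized like the populations the analyses are
  meant for.
* **Operant agents** choose by softmax over the reward-augmented predictor,
  with partial sums over whatever history exists on early trials.  Rewards
  are Bernoulli per arm with configurable success probabilities and payoff
  values ({0, 1} by default; zero-mean ±1 payoffs are used for the
  permutation control, see below).

What the generators do *not* emulate: slow drifts in strategy (except via
the explicit piecewise generator), lapses, response-time structure, and the
specific reward schedules of any published operant experiment.  Green tests
therefore certify the statistical machinery on data that satisfy the model
family, not any claim about particular human datasets.

For lag-1 sources the irreducible ("Bayes") next-symbol error has a closed
form via the two-state Markov chain of the previous symbol
(`bayes_error_lag1`); predictor near-optimality is judged against it.

## Cross-validation

Heterogeneous regime: per participant, design rows are split into 10
*contiguous* folds; parameters are fit on nine and errors measured on the
held-out fold, then averaged across folds, then participants.  Contiguity
preserves the sequential dependence being modeled — randomly shuffled folds
would leak each test trial's immediate history into training (a config flag
enables shuffled folds for sensitivity checks).  Homogeneous regime:
leave-one-participant-out — one parameter set fit on all other participants'
stacked designs (or pooled pattern tables), evaluated on every eligible
trial of the held-out participant.  Test-trial histories always use the
participant's true preceding choices, never model rollouts.  Parameter-free
models (negative recency, balance) skip fitting but are scored on the same
test trials for comparability, and give identical results in both regimes.

Nearest-neighbor predictors store every (length-L window → next symbol)
pair from the training trials.  Among training patterns at minimal distance
(Hamming, or unit-cost edit distance via `edlib`) the majority next symbol
wins; exact vote ties fall back to alternation from the window's last
symbol — the model family gives no tie rule, so the fallback is the
best-supported parameter-free bias.  Windows are encoded as integers, so
Hamming distances are popcounts and edit distances are precomputed once per
L over the 2^L × 2^L pattern table (L ≤ 20 enforced).

Memory length is selected by minimizing cross-validated error over a grid,
ties to the smallest L.

## Heterogeneity summaries

Per-lag statistics over the population: mean μ(β_k), quadratic mean
√E[β_k²] (large when effects are strong regardless of sign), SD σ(β_k), and
SNR = |μ|/σ (large when the population is homogeneous).  SD uses the sample
(n−1) denominator — standard for between-participant inference — under
which `qmean² = μ² + σ²(n−1)/n` holds exactly (asserted in tests).  A
population-SD variant of the SNR would be `snr · √((n−1)/n)`; both are
derivable from the reported columns.  Exactly constant columns report
σ = 0 and SNR = ∞ rather than floating-point fuzz.  Uncertainty comes from
resampling *participants* (not trials) with replacement, B = 100 by
default, with percentile intervals at the Bonferroni-corrected level
(m defaults to the number of lags).  Task comparisons resample the two
populations independently.

## Stationarity scan

The training sample `k` trials before the test trial gets weight
`(1 − η)·η^k` (`0⁰ = 1`, so η = 0 keeps only the most recent trial; the
weights sum to `1 − η^n`).  Prediction starts at the middle sample and
walks to the end; the model is refit every `refit_stride` trials (default
10 — a ~26× grid times ~50 refits per sequence is the tractable
configuration; stride 1 reproduces the literal per-trial protocol and is a
flag).  The selected η is the argmin of mean one-step-ahead error;
*exact* ties — common, because near-uniform weightings produce literally
identical hard calls — resolve to the largest η, i.e. the longest timescale
consistent with the minimal error.

The grid is η = 0 plus 25 values whose recency weights `1 − η` are
log-spaced over [10⁻⁶, 1).  Log-spacing the *recency weight* rather than η
itself makes the associated timescales `1/(1 − η)` span 1 to 10⁶ trials;
log-spacing η directly would cap the expressible timescale at ≈ 2.4 trials,
which cannot represent the hundreds-of-trials stability the scan is
designed to detect.  The reported timescale is `1/(1 − η)`; the alternative
reading `η/(1 − η)` differs by at most one trial and is available as a
one-liner.

## Permutation control for the reward model

Shuffling rewards within a participant destroys the reward-choice
contingency, so α̂ collapses toward zero while the sequential structure
remains.  One subtlety dictates the control's reward design: with
mean-`r̄ ≠ 0` rewards, the marginalized interaction `E[s·r | s] = r̄·s` loads
onto β̂ after shuffling, so β̂ would *not* be preserved.  The control
therefore uses zero-mean ±1 payoffs on a non-contingent (0.5, 0.5)
schedule, for which `E[s·r | s] = 0` and preservation is exact up to the
mild attenuation described next.  Even then, the shuffled fit omits a real
source of variance (the α terms it can no longer see), which attenuates
β̂ by the usual omitted-covariate logistic factor — about 10% at the
simulated effect sizes; the tests budget for it.

## Simulation sizes and numerical choices

The validation suite uses: 30 × 10,000 fair-coin trials for the
conditional-probability null; 200 agents × 1,000 trials (truth
β = (0.3, −0.8, 0.4)) for recovery; the canonical 30 × 1,000 heterogeneous
population for the pooled-vs-individual signature and the CV regime gap
(evaluated at the generative horizon L = 3); 10 × 10,000 lag-1 sources
(β = (0.3, −0.8)) for Bayes-error comparisons; 20 paired seeds of
1,000-trial stationary (β₁ = 1.5) vs mid-sequence sign-flip sequences for
the stationarity scan; 10,000-trial operant sessions (TD limit γ = 0.8,
T = 1, arms 0.8/0.2) for reward-weight recovery; and ten 30-trial fair
instances for the grid-search oracle.  These sizes make every directional
effect several Monte-Carlo standard errors wide while keeping the whole
suite in the minutes range.

Degenerate inputs are contracts, not crashes: constant responses raise a
degenerate-data error (unless ridged), empty nearest-neighbor training sets
raise a state error, constant predictions yield an undefined (NaN)
calibration correlation, and collinear reward regressors (e.g. constant
rewards) flag the fit and name the offending columns.

## Known limitations

* **Feedback-induced estimation bias.**  Because the sequence feeds back
  into its own design, the MLE of the lag coefficients carries a genuine
  O(1/n) negative bias — the logistic analogue of the classical downward
  bias of autoregressive-coefficient estimates.  Measured: ≈ −0.015 on β₁
  at n = 1,000, shrinking to ≈ −0.003 at n = 4,000, while a control with
  i.i.d. ±1 designs at the same n shows none.  At n = 1,000 this bias is
  resolvable by a few hundred Monte-Carlo replicates, i.e. recovery is
  *consistent but not exactly unbiased* at that length; analyses that need
  bias below 0.01 should use longer sequences.
* **Anti-predictive leave-one-out pooling.**  On a population whose only
  short-lag structure is a mean-zero heterogeneous β₁, the pooled-others
  slope is approximately `κ(N·m̄ − β₁ᵢ)/(N−1)` for held-out participant i —
  it *anti-correlates* with that participant's own effect, and hard calls
  amplify any nonzero slope.  Homogeneous CV error is therefore at or above
  0.5 in this setting (not asymptotically 0.5), a sharpened form of the
  heterogeneous-vs-homogeneous gap.  This is a property of LOO pooling with
  sign-balanced heterogeneity, not an implementation artifact.
* The two-stage heterogeneity analysis (fit, then summarize) is not a
  mixed-effects model; between-participant SDs include per-participant
  sampling noise (visible as SNR < ∞ even for truth-common coefficients).
* Only binary choice is supported, by design.
* The edit-distance predictor is a plain nearest-neighbor-by-Levenshtein
  rule over fixed-length windows; published pattern-matching variants with
  weighted distances or variable windows are out of scope.
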