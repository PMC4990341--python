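# seqfx

Sequential-effect analysis of binary choice behavior.

When people are asked to produce a "random" sequence of Heads and Tails
(random sequence generation, RSG), or repeatedly choose between two rewarded
alternatives (operant learning, OL), their current choice depends
systematically on their recent choices — and, in operant tasks, on recent
rewards.  `seqfx` quantifies these dependencies with lagged logistic choice
models, measures how strongly they differ between individuals, tests how well
they predict the next symbol, and asks whether they are stable over a
session.

## The model

The probability of choosing symbol 1 on trial *t* is logistic in a linear
"value" of the recent history:

    Pr(a_t = 1) = 1 / (1 + exp(−ΔQ_t)),
    ΔQ_t = β₀ + Σ_{k=1..L} β_k s_{t−k},          s_{t−k} = a_{t−k} − (1 − a_{t−k}) ∈ {−1, +1}

so β₁ < 0 is an alternation bias (negative recency), β₁ > 0 inertia, and
β₀ an overall preference.  For operant data the predictor gains
reward-choice interaction terms,

    ΔQ_t = β₀ + Σ_{k=1..L} s_{t−k} (α_k r_{t−k} + β_k),

where the α_k play the role of learned action values (α_k = γ^k / T recovers
softmax temporal-difference learning) and the β_k are the residual,
reward-independent sequential effects.

Around this core the package provides:

* **sequences** — long-format CSV/TSV I/O and signed-lag design matrices;
* **generators** — fair coins, heterogeneous populations of lagged-logistic
  agents with known ground truth, and two-armed-bandit sessions;
* **logistic** — weighted maximum likelihood with standard errors, Wald
  tests, Bonferroni-corrected intervals, plus a brute-force grid-search
  reference maximizer;
* **predictors** — five next-symbol models (negative recency, balance,
  Hamming nearest neighbor, edit-distance nearest neighbor, logistic) under
  within-participant 10-fold CV ("heterogeneous") and
  leave-one-participant-out CV ("homogeneous"), memory-length selection and
  a 20-bin calibration curve;
* **randomness** — model-free deviation statistics (lagged conditional
  probabilities, Heads counts in windows of 10, alternation by run length)
  with Monte-Carlo chance bands;
* **heterogeneity** — population summaries per coefficient: mean μ(β_k),
  quadratic mean, SD, and signal-to-noise ratio |μ|/σ with bootstrap CIs;
* **stationarity** — exponentially discounted refits (weight (1−η)·η^k)
  scanned over η, selecting the recency timescale 1/(1−η) that best predicts
  held-out trials;
* **rl** — joint α/β estimation for operant data and the RSG-vs-OL
  comparison of reward-free coefficients.

## Worked example

Simulate a population with a heterogeneous, mean-zero lag-1 effect
(β₁ ~ N(0,1)) and a common lag-3 alternation bias (β₃ = −0.4), then look at
it through the pooled and the per-participant lens:

```python
from seqfx import (PopulationSpec, generate_population, build_lag_design,
                   stack_designs, fit_logistic_mle, fit_population, summarize,
                   evaluate_heterogeneous, evaluate_homogeneous)

spec = PopulationSpec(n_participants=30, n_trials=1000, L_gen=3,
                      beta_mean=[0.0, 0.0, 0.0, -0.4],
                      beta_sd=[0.0, 1.0, 0.0, 0.0], seed=42)
seqs, truth = generate_population(spec)

pooled = fit_logistic_mle(stack_designs([build_lag_design(s, 3) for s in seqs]))
coef = fit_population(seqs, 3)
print(f"pooled beta_1: {pooled.beta_hat[1]:+.3f}")
print(f"mean per-participant |beta_1|: {coef['beta_1'].abs().mean():.3f}")
print(summarize(coef).as_frame().round(3).to_string(index=False))
```

prints

```
pooled beta_1: -0.140
mean per-participant |beta_1|: 0.687
 lag     mu  qmean  sigma   snr
   0 -0.007  0.071  0.072 0.097
   1 -0.198  0.843  0.834 0.237
   2 -0.007  0.104  0.106 0.066
   3 -0.394  0.410  0.116 3.399
```

The pooled fit sees almost no lag-1 effect (−0.14) even though every
individual has a substantial one (mean magnitude 0.69, quadratic mean 0.84):
heterogeneous effects of opposite signs cancel in the population average,
while the common lag-3 bias survives pooling and has a high SNR (3.4).  The
same dissociation shows up in predictive power —

```python
het = evaluate_heterogeneous("logistic", seqs, 3)
hom = evaluate_homogeneous("logistic", seqs, 3)
print(f"heterogeneous CV error: {het.error_rate:.3f}")
print(f"homogeneous  CV error: {hom.error_rate:.3f}")
```

```
heterogeneous CV error: 0.325
homogeneous  CV error: 0.406
```

— per-participant parameters predict the next symbol far better than one
shared parameter set.

A command-line interface mirrors the library
(`seqfx simulate|fit|stats|predict|heterogeneity|stationarity|rl-fit|compare`);
see `seqfx --help`.

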