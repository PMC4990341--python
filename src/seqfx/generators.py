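"""Synthetic populations with the statistical structure the analyses assume.

Three families of generators:

* fair coins — the i.i.d. Bernoulli(0.5) null against which deviations from
  randomness are measured;
* lagged-logistic agents — sequences produced generatively from the choice
  model ``Pr(a_t=1) = σ(β₀ + Σ_k β_k s_{t-k})``, with per-participant
  coefficient vectors drawn from a configurable population distribution
  (Normal by default);
* operant (two-armed bandit) agents — choices driven by the reward-augmented
  predictor ``ΔQ = β₀ + Σ_k s_{t-k}(α_k r_{t-k} + β_k)`` with stochastic
  rewards; the TD-limit parameterization ``α_k = γ^k / T`` recovers softmax
  temporal-difference learning when the reward-free β vanish.

All generators are bit-reproducible given a seed.  Logistic agents warm up
with ``L`` fair-coin draws so that no arbitrary initial history is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._errors import ValidationError
from .sequences import ChoiceSequence

__all__ = [
    "PopulationSpec",
    "OperantAgentSpec",
    "generate_fair_coin",
    "generate_logistic_agent",
    "generate_drifting_agent",
    "generate_population",
    "generate_operant_session",
    "stationary_alternation_rate",
    "bayes_error_lag1",
]


def generate_fair_coin(
    n_trials: int, n_sequences: int = 1, seed: int | None = None
) -> list[ChoiceSequence]:
    """i.i.d. equiprobable binary sequences (the chance reference)."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n_sequences, n_trials), dtype=np.int8)
    return [
        ChoiceSequence(participant_id=f"coin{i:03d}", choices=bits[i])
        for i in range(n_sequences)
    ]


def _simulate_logistic(beta_for_trial, n_trials: int, L: int, rng) -> np.ndarray:
    """Core generative loop: warm-up of L fair draws, then the logistic rule.

    ``beta_for_trial(t)`` returns the coefficient vector (length L+1) in force
    on 0-based trial ``t``.
    """
    a = np.empty(n_trials, dtype=np.int8)
    n_warm = min(L, n_trials)
    a[:n_warm] = rng.integers(0, 2, size=n_warm)
    u = rng.random(n_trials)
    s = np.empty(n_trials)
    s[:n_warm] = 2.0 * a[:n_warm] - 1.0
    for t in range(n_warm, n_trials):
        beta = beta_for_trial(t)
        # s_{t-1}..s_{t-L}, most recent first, matching beta[1..L]
        dq = beta[0] + float(beta[1:] @ s[t - L : t][::-1])
        a[t] = u[t] < expit(dq)
        s[t] = 2.0 * a[t] - 1.0
    return a


def _check_beta(beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or beta.size < 1 or not np.isfinite(beta).all():
        raise ValidationError("beta must be a finite 1-D coefficient vector")
    return beta


def generate_logistic_agent(
    beta,
    n_trials: int,
    seed: int | None = None,
    participant_id: str = "agent",
) -> ChoiceSequence:
    """Sequence from a single lagged-logistic agent with fixed ``beta``.

    ``beta = (β₀, β₁, .., β_L)``; the first ``L`` choices are fair draws.
    """
    beta = _check_beta(beta)
    L = beta.size - 1
    if n_trials <= L:
        raise ValidationError(f"n_trials must exceed L={L}")
    rng = np.random.default_rng(seed)
    a = _simulate_logistic(lambda t: beta, n_trials, L, rng)
    return ChoiceSequence(participant_id=participant_id, choices=a)


def generate_drifting_agent(
    segments: list[tuple[int, np.ndarray]],
    seed: int | None = None,
    participant_id: str = "drifter",
) -> ChoiceSequence:
    """Agent whose coefficients change between contiguous segments.

    ``segments`` is a list of ``(n_trials, beta)`` pairs; history carries
    across segment boundaries (a single continuous sequence).  All betas must
    share the same length.
    """
    betas = [_check_beta(b) for _, b in segments]
    lens = [int(n) for n, _ in segments]
    if not segments or min(lens) < 1:
        raise ValidationError("segments must have positive lengths")
    if len({b.size for b in betas}) != 1:
        raise ValidationError("all segment betas must share one horizon")
    L = betas[0].size - 1
    edges = np.cumsum(lens)
    n_trials = int(edges[-1])

    def beta_for_trial(t: int) -> np.ndarray:
        return betas[int(np.searchsorted(edges, t, side="right"))]

    rng = np.random.default_rng(seed)
    a = _simulate_logistic(beta_for_trial, n_trials, L, rng)
    return ChoiceSequence(participant_id=participant_id, choices=a)


@dataclass
class PopulationSpec:
    """Population of lagged-logistic agents with Normal coefficient spread.

    ``beta_mean`` and ``beta_sd`` have length ``L_gen + 1`` (intercept first);
    each participant's coefficient vector is drawn componentwise from
    ``Normal(beta_mean, beta_sd)``.
    """

    n_participants: int
    n_trials: int
    L_gen: int
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.beta_mean = np.asarray(self.beta_mean, dtype=float)
        self.beta_sd = np.asarray(self.beta_sd, dtype=float)
        want = self.L_gen + 1
        if self.beta_mean.size != want or self.beta_sd.size != want:
            raise ValidationError(f"beta_mean/beta_sd must have length {want}")
        if (self.beta_sd < 0).any():
            raise ValidationError("beta_sd entries must be >= 0")
        if self.n_participants < 1 or self.n_trials <= self.L_gen:
            raise ValidationError("need n_participants >= 1 and n_trials > L_gen")


def generate_population(
    spec: PopulationSpec,
) -> tuple[list[ChoiceSequence], pd.DataFrame]:
    """Generate a heterogeneous population plus its ground-truth coefficients.

    Returns ``(sequences, truth)`` where ``truth`` has one row per participant
    and columns ``beta_0 .. beta_L``.
    """
    rng = np.random.default_rng(spec.seed)
    betas = rng.normal(
        spec.beta_mean, spec.beta_sd, size=(spec.n_participants, spec.L_gen + 1)
    )
    seqs = []
    for i in range(spec.n_participants):
        pid = f"p{i:03d}"
        child = np.random.default_rng(rng.integers(0, 2**31))
        a = _simulate_logistic(
            lambda t, b=betas[i]: b, spec.n_trials, spec.L_gen, child
        )
        seqs.append(ChoiceSequence(participant_id=pid, choices=a))
    truth = pd.DataFrame(
        betas,
        index=[s.participant_id for s in seqs],
        columns=[f"beta_{k}" for k in range(spec.L_gen + 1)],
    )
    truth.index.name = "participant"
    return seqs, truth


@dataclass
class OperantAgentSpec:
    """Two-armed-bandit agent driven by the reward-augmented choice model.

    ``alpha`` (length L) weights the reward-choice interactions
    ``s_{t-k} r_{t-k}``; ``beta`` (length L+1, intercept first) the reward-free
    sequential terms.  ``reward_probs = (p_A, p_B)`` are the success
    probabilities of arms 1 and 0; a success pays ``reward_values[1]`` and a
    failure ``reward_values[0]`` (defaults: Bernoulli {0, 1} payoffs).
    """

    alpha: np.ndarray
    beta: np.ndarray
    reward_probs: tuple[float, float] = (0.5, 0.5)
    reward_values: tuple[float, float] = (0.0, 1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.size != self.alpha.size + 1:
            raise ValidationError("beta must have length len(alpha) + 1")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValidationError("alpha/beta must be finite")
        if not all(0.0 <= p <= 1.0 for p in self.reward_probs):
            raise ValidationError("reward_probs must lie in [0, 1]")

    @property
    def L(self) -> int:
        return int(self.alpha.size)

    @classmethod
    def td_limit(
        cls,
        gamma: float,
        T: float,
        L: int,
        reward_probs: tuple[float, float] = (0.5, 0.5),
        reward_values: tuple[float, float] = (0.0, 1.0),
        seed: int | None = None,
    ) -> "OperantAgentSpec":
        """TD-learning limit: ``α_k = γ^k / T``, all β = 0."""
        if not 0.0 < gamma < 1.0:
            raise ValidationError("gamma must be in (0, 1)")
        if T <= 0:
            raise ValidationError("temperature T must be > 0")
        alpha = gamma ** np.arange(1, L + 1) / T
        return cls(
            alpha=alpha,
            beta=np.zeros(L + 1),
            reward_probs=reward_probs,
            reward_values=reward_values,
            seed=seed,
        )


def generate_operant_session(
    spec: OperantAgentSpec,
    n_trials: int,
    seed: int | None = None,
    participant_id: str = "agent",
    block_id: str | None = None,
) -> ChoiceSequence:
    """Simulate one operant block: softmax choices, stochastic rewards.

    Early trials use whatever history is available (partial sums over
    ``k <= t``); rewards depend on the chosen arm's success probability.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.L
    a = np.empty(n_trials, dtype=np.int8)
    s = np.empty(n_trials)
    r = np.empty(n_trials)
    u_choice = rng.random(n_trials)
    u_reward = rng.random(n_trials)
    lo, hi = spec.reward_values
    p_arm = {1: spec.reward_probs[0], 0: spec.reward_probs[1]}
    for t in range(n_trials):
        kmax = min(L, t)
        dq = spec.beta[0]
        if kmax:
            s_hist = s[t - kmax : t][::-1]
            r_hist = r[t - kmax : t][::-1]
            dq += float(
                s_hist @ (spec.alpha[:kmax] * r_hist + spec.beta[1 : kmax + 1])
            )
        a[t] = u_choice[t] < expit(dq)
        s[t] = 2.0 * a[t] - 1.0
        r[t] = hi if u_reward[t] < p_arm[int(a[t])] else lo
    return ChoiceSequence(
        participant_id=participant_id, choices=a, rewards=r, block_id=block_id
    )


def _lag1_chain(beta) -> tuple[float, float, float]:
    """Stationary lag-1 quantities: (P(1|prev=1), P(1|prev=0), π₁)."""
    beta = _check_beta(beta)
    if beta.size != 2:
        raise ValidationError("closed forms require a lag-1 model (β₀, β₁)")
    p11 = expit(beta[0] + beta[1])
    p10 = expit(beta[0] - beta[1])
    pi1 = p10 / (1.0 - p11 + p10)
    return float(p11), float(p10), float(pi1)


def stationary_alternation_rate(beta) -> float:
    """Long-run alternation probability of a lag-1 logistic agent."""
    p11, p10, pi1 = _lag1_chain(beta)
    return pi1 * (1.0 - p11) + (1.0 - pi1) * p10


def bayes_error_lag1(beta) -> float:
    """Irreducible next-symbol prediction error of a lag-1 logistic source.

    ``E[min(p, 1-p)]`` under the stationary distribution of the previous
    symbol — the floor against which predictor performance is judged.
    """
    p11, p10, pi1 = _lag1_chain(beta)
    return pi1 * min(p11, 1.0 - p11) + (1.0 - pi1) * min(p10, 1.0 - p10)
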