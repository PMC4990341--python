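"""Reward-augmented sequential choice model for operant learning.

The choice probability is the logistic rule with linear predictor

    ΔQ = β₀ + Σ_{k=1..L} s_{t-k} (α_k r_{t-k} + β_k),

so the reward-choice interaction weights α_k play the role of learned action
values (α_k = γ^k / T recovers softmax TD learning) while the β_k capture the
residual, reward-independent sequential effects.  α and β are estimated
jointly in a single maximum-likelihood fit over the 2L + 1 regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DegenerateDataError, InsufficientDataError, ValidationError
from .heterogeneity import HeterogeneitySummary, summarize
from .logistic import _newton_logistic
from .sequences import (
    ChoiceSequence,
    LagDesign,
    build_lag_design,
    group_by_participant,
    stack_designs,
)

__all__ = ["RLFit", "fit_rl", "residual_sequential_effects", "shuffle_rewards"]


@dataclass
class RLFit:
    """Joint fit of reward-interaction (α) and reward-free (β) weights.

    ``beta_hat[0]`` is the intercept; ``alpha_hat[k-1]`` weights
    ``s_{t-k} r_{t-k}``.  ``collinear`` flags designs in which the reward
    interactions are (nearly) linear in the plain signed lags, e.g. when
    rewards are constant.
    """

    beta_hat: np.ndarray
    alpha_hat: np.ndarray
    se_beta: np.ndarray
    se_alpha: np.ndarray
    ci_lo_beta: np.ndarray
    ci_hi_beta: np.ndarray
    ci_lo_alpha: np.ndarray
    ci_hi_alpha: np.ndarray
    wald_p_beta: np.ndarray
    wald_p_alpha: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    collinear: bool

    @property
    def L(self) -> int:
        return int(self.alpha_hat.size)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of near-collinear columns, detected via SVD rank deficiency."""
    u, sv, vt = np.linalg.svd(X, full_matrices=False)
    bad = sv < sv[0] * 1e-8
    if not bad.any():
        return []
    # columns loading on the null-space directions
    load = np.abs(vt[bad]).max(axis=0)
    return [int(i) for i in np.flatnonzero(load > 0.1)]


def fit_rl(design: LagDesign, ci_alpha: float = 0.05) -> RLFit:
    """Fit the reward-augmented model by joint maximum likelihood.

    ``design`` must carry ``reward_lags``.  On collinearity between reward
    and choice regressors the fit proceeds with a tiny ridge and is flagged;
    a warning names the offending columns.
    """
    if design.reward_lags is None:
        raise ValidationError("fit_rl requires a design with reward_lags")
    L = design.L
    if design.n_obs < 2 * L + 2:
        raise InsufficientDataError(
            f"need at least 2L+2={2 * L + 2} rows, got {design.n_obs}"
        )
    X = design.matrix(include_rewards=True)
    names = (
        ["intercept"]
        + [f"s[t-{k}]" for k in range(1, L + 1)]
        + [f"s*r[t-{k}]" for k in range(1, L + 1)]
    )
    bad = _collinear_columns(X)
    collinear = bool(bad)
    ridge = 0.0
    if collinear:
        warnings.warn(
            "collinear regressors: " + ", ".join(names[i] for i in bad)
            + " — fitting with a small ridge; estimates are not separately "
            "identified"
        )
        ridge = 1e-6
    beta_full, cov, ll, converged = _newton_logistic(
        X, design.responses, weights=design.weights, ridge=ridge
    )
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(1.0 - ci_alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta_full / se, np.inf * np.sign(beta_full))
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    b = slice(0, L + 1)
    a = slice(L + 1, 2 * L + 1)
    return RLFit(
        beta_hat=beta_full[b],
        alpha_hat=beta_full[a],
        se_beta=se[b],
        se_alpha=se[a],
        ci_lo_beta=beta_full[b] - z * se[b],
        ci_hi_beta=beta_full[b] + z * se[b],
        ci_lo_alpha=beta_full[a] - z * se[a],
        ci_hi_alpha=beta_full[a] + z * se[a],
        wald_p_beta=p[b],
        wald_p_alpha=p[a],
        loglik=ll,
        n_obs=design.n_obs,
        converged=converged and not collinear,
        collinear=collinear,
    )


def residual_sequential_effects(
    seqs, L: int
) -> tuple[pd.DataFrame, HeterogeneitySummary]:
    """Population summary of the reward-independent β coefficients.

    Fits the reward-augmented model per participant (blocks pooled as
    stacked designs) and summarizes the β columns only — the residual
    sequential effects after the reward interactions have absorbed the
    value-driven component.
    """
    groups = group_by_participant(list(seqs))
    rows = {}
    flags = {}
    for pid, blocks in groups.items():
        try:
            design = stack_designs(
                [build_lag_design(b, L, include_rewards=True) for b in blocks]
            )
            fit = fit_rl(design)
            rows[pid] = fit.beta_hat
            flags[pid] = fit.converged
        except (DegenerateDataError, InsufficientDataError) as exc:
            warnings.warn(f"participant {pid!r}: {exc} — excluded")
            rows[pid] = np.full(L + 1, np.nan)
            flags[pid] = False
    coef = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"beta_{k}" for k in range(L + 1)]
    )
    coef.index.name = "participant"
    coef["converged"] = pd.Series(flags)
    return coef, summarize(coef)


def shuffle_rewards(seq: ChoiceSequence, seed: int | None = None) -> ChoiceSequence:
    """Permutation control: rewards shuffled within the sequence.

    Destroys the reward-choice contingency while preserving the choice
    sequence and the marginal reward distribution; refitting should collapse
    α̂ toward zero.
    """
    if seq.rewards is None:
        raise ValidationError("sequence has no rewards to shuffle")
    rng = np.random.default_rng(seed)
    return ChoiceSequence(
        participant_id=seq.participant_id,
        choices=seq.choices.copy(),
        rewards=rng.permutation(seq.rewards),
        block_id=seq.block_id,
    )
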