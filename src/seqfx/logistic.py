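"""Lagged logistic choice model: probability rule, weighted MLE, Wald tests.

The model: the probability of choosing symbol 1 on trial ``t`` is
``Pr(a_t = 1) = 1 / (1 + exp(-ΔQ_t))`` with the linear predictor
``ΔQ_t = β₀ + Σ_{k=1..L} β_k s_{t-k}`` over the signed history codes
``s = ±1`` (see :mod:`seqfx.sequences`).  Estimation is Newton/IRLS
maximum likelihood with optional non-negative prior weights (used by the
discounted stationarity scan) and an optional ridge penalty that is off by
default and exists solely to stabilize degenerate, tiny-effective-sample
weighted fits.

Perfect separation does not raise: coefficients are capped at ``|β| = 20``
and the fit is flagged ``converged=False`` so downstream cross-validation can
still use its (saturated) predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from ._errors import DegenerateDataError, InsufficientDataError, ValidationError
from .sequences import LagDesign

__all__ = [
    "LogisticFit",
    "choice_probability",
    "fit_logistic_mle",
    "bonferroni_level",
    "grid_search_mle",
    "predict_records",
]

#: cap on |coefficient| used when the likelihood has no interior maximum
BETA_CAP = 20.0


def choice_probability(delta_q):
    """Probability of choosing symbol 1 given the linear predictor ΔQ.

    Vectorized, numerically stable for |ΔQ| up to ~700.
    """
    delta_q = np.asarray(delta_q, dtype=float)
    if np.isnan(delta_q).any():
        raise ValidationError("delta_q contains NaN")
    out = expit(delta_q)
    return float(out) if out.ndim == 0 else out


def bonferroni_level(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test level ``alpha / m`` for ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return alpha / m


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of the lagged logistic model.

    ``beta_hat[0]`` is the intercept β₀ and ``beta_hat[k]`` the coefficient on
    ``s_{t-k}``.  Confidence bounds are at the (already corrected) level
    ``ci_level`` supplied to the fitter.
    """

    beta_hat: np.ndarray
    se: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    wald_p: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    ci_level: float

    @property
    def L(self) -> int:
        return int(self.beta_hat.size - 1)


def _loglik(X, y, beta, w):
    eta = X @ beta
    # log p for y=1, log(1-p) for y=0, stable via logaddexp
    ll = -(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1.0 - y))
    return float(np.sum(w * ll))


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    cap: float = BETA_CAP,
):
    """Newton/IRLS maximizer of the weighted Bernoulli log-likelihood.

    Returns (beta, cov, loglik, converged).  Score convergence tolerance and
    iteration cap follow standard GLM practice.
    """
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if ridge == 0.0:
        eff = y[w > 0]
        if eff.size == 0 or np.all(eff == eff[0]):
            raise DegenerateDataError(
                "responses are all identical; the unpenalized MLE does not exist"
            )
    beta = np.zeros(p)
    ll = _loglik(X, y, beta, w) - 0.5 * ridge * beta @ beta
    converged = False
    for _ in range(max_iter):
        mu = expit(X @ beta)
        score = X.T @ (w * (y - mu)) - ridge * beta
        if np.linalg.norm(score) < tol:
            converged = True
            break
        wv = w * mu * (1.0 - mu)
        H = (X * wv[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving keeps the penalized log-likelihood non-decreasing
        new_beta = np.clip(beta + step, -cap, cap)
        new_ll = _loglik(X, y, new_beta, w) - 0.5 * ridge * new_beta @ new_beta
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = np.clip(beta + step, -cap, cap)
            new_ll = _loglik(X, y, new_beta, w) - 0.5 * ridge * new_beta @ new_beta
            halvings += 1
        if np.allclose(new_beta, beta, rtol=0, atol=1e-12):
            # stuck on the cap boundary or a flat direction
            beta = new_beta
            ll = new_ll
            break
        beta, ll = new_beta, new_ll
    if np.any(np.abs(beta) >= cap - 1e-9):
        converged = False  # separation: likelihood maximized on the boundary
    mu = expit(X @ beta)
    wv = w * mu * (1.0 - mu)
    H = (X * wv[:, None]).T @ X + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, _loglik(X, y, beta, w), converged


def fit_logistic_mle(
    design: LagDesign,
    weights: np.ndarray | None = None,
    ridge: float = 0.0,
    ci_alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit the lagged logistic model by (weighted) maximum likelihood.

    Parameters
    ----------
    design : LagDesign
        Responses and signed-lag regressors; ``design.weights`` is used when
        ``weights`` is not given.
    weights : array, optional
        Non-negative per-row prior weights (e.g. exponential recency weights).
    ridge : float
        L2 penalty; 0 (plain ML) everywhere except degenerate discounted fits.
    ci_alpha : float
        Two-sided level for the reported confidence bounds — pass a
        Bonferroni-corrected value (:func:`bonferroni_level`) when testing
        many lags.

    Raises
    ------
    DegenerateDataError
        If all (positively weighted) responses are identical and ``ridge`` is 0.
    InsufficientDataError
        If there are fewer than ``L + 2`` rows.
    """
    X = design.matrix()
    y = design.responses
    if weights is None:
        weights = design.weights
    if design.n_obs < design.L + 2:
        raise InsufficientDataError(
            f"need at least L+2={design.L + 2} rows, got {design.n_obs}"
        )
    beta, cov, ll, converged = _newton_logistic(
        X, y, weights=weights, ridge=ridge, tol=tol, max_iter=max_iter
    )
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(1.0 - ci_alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    wald_p = 2.0 * stats.norm.sf(np.abs(zstat))
    return LogisticFit(
        beta_hat=beta,
        se=se,
        ci_lo=beta - z * se,
        ci_hi=beta + z * se,
        wald_p=wald_p,
        loglik=ll,
        n_obs=design.n_obs,
        converged=converged,
        ci_level=ci_alpha,
    )


def predict_records(beta: np.ndarray, design: LagDesign, include_rewards: bool = False):
    """Per-trial predictions under coefficient vector ``beta``.

    Returns ``(delta_q, p_heads, hard_call)`` arrays.  The hard call at the
    tie ``p = 0.5`` is symbol 1, deterministically.
    """
    X = design.matrix(include_rewards=include_rewards)
    beta = np.asarray(beta, dtype=float)
    if beta.size != X.shape[1]:
        raise ValidationError(
            f"beta length {beta.size} does not match design columns {X.shape[1]}"
        )
    dq = X @ beta
    p = expit(dq)
    return dq, p, (p >= 0.5).astype(np.int8)


def grid_search_mle(
    design: LagDesign, step: float = 0.01, bound: float = 3.0
) -> np.ndarray:
    """Brute-force grid-search maximizer of the log-likelihood (L = 1 only).

    An independent reference for validating the Newton fitter: evaluates the
    exact Bernoulli log-likelihood on a regular (β₀, β₁) grid with spacing
    ``step`` over ``[-bound, bound]²`` and returns the argmax.  Exhaustive and
    slow by design; intended for tiny instances.
    """
    if design.L != 1:
        raise ValidationError("grid_search_mle supports L=1 designs only")
    grid = np.arange(-bound, bound + step / 2, step)
    y = design.responses
    s = design.signed_lags[:, 0]
    b0 = grid[:, None, None]
    b1 = grid[None, :, None]
    eta = b0 + b1 * s[None, None, :]
    ll = -(
        np.logaddexp(0.0, -eta) * y[None, None, :]
        + np.logaddexp(0.0, eta) * (1.0 - y[None, None, :])
    ).sum(axis=2)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return np.array([grid[i], grid[j]])
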