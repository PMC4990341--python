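"""Population summaries of per-participant coefficients.

The two-stage analysis: fit the lagged logistic model to each participant
separately, then summarize each coefficient across the population by its
mean ``μ(β_k)``, quadratic mean ``√E[β_k²]`` (large when effects are strong
regardless of sign), standard deviation ``σ(β_k)``, and signal-to-noise ratio
``SNR = |μ|/σ`` (large when the population is homogeneous).  Uncertainty is
quantified by bootstrap resampling of participants, with Bonferroni-corrected
percentile intervals.

SD uses the sample (n−1) denominator throughout, so the identity
``qmean² = μ² + σ²·(n−1)/n`` holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import DegenerateDataError, ValidationError
from .logistic import bonferroni_level, fit_logistic_mle
from .sequences import ChoiceSequence, build_lag_design, group_by_participant, stack_designs

__all__ = [
    "HeterogeneitySummary",
    "fit_population",
    "summarize",
    "bootstrap_ci",
    "compare_tasks",
]

_STATS = ("mu", "qmean", "sigma", "snr")


@dataclass
class HeterogeneitySummary:
    """Per-lag population statistics of a coefficient matrix.

    Arrays are indexed by lag ``k = 0..L`` (0 = intercept).  ``snr`` is
    ``inf`` where the population SD is exactly zero.
    """

    mu: np.ndarray
    qmean: np.ndarray
    sigma: np.ndarray
    snr: np.ndarray
    n_participants: int

    @property
    def n_lags(self) -> int:
        return int(self.mu.size)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": np.arange(self.n_lags),
                "mu": self.mu,
                "qmean": self.qmean,
                "sigma": self.sigma,
                "snr": self.snr,
            }
        )


def fit_population(
    seqs: Iterable[ChoiceSequence],
    L: int,
    ci_alpha: float = 0.05,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Per-participant coefficient matrix (participants × lags 0..L).

    Sequences sharing a participant id (operant blocks) are pooled as stacked
    designs; histories never cross block boundaries.  Returns a DataFrame
    with columns ``beta_0..beta_L`` plus a boolean ``converged`` column;
    non-converged rows are kept but flagged (summaries exclude them).
    """
    groups = group_by_participant(list(seqs))
    level = bonferroni_level(ci_alpha, m_tests) if m_tests else ci_alpha
    rows = {}
    flags = {}
    for pid, blocks in groups.items():
        try:
            design = stack_designs([build_lag_design(b, L) for b in blocks])
            fit = fit_logistic_mle(design, ci_alpha=level)
            rows[pid] = fit.beta_hat
            flags[pid] = fit.converged
        except DegenerateDataError:
            warnings.warn(
                f"participant {pid!r}: degenerate data, excluded from summaries"
            )
            rows[pid] = np.full(L + 1, np.nan)
            flags[pid] = False
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"beta_{k}" for k in range(L + 1)]
    )
    out.index.name = "participant"
    out["converged"] = pd.Series(flags)
    return out


def _coef_array(coeff_matrix) -> np.ndarray:
    """Coefficient rows as a float array, dropping flagged/NaN rows."""
    if isinstance(coeff_matrix, pd.DataFrame):
        df = coeff_matrix
        if "converged" in df.columns:
            df = df.loc[df["converged"].astype(bool), :].drop(columns="converged")
        arr = df.to_numpy(dtype=float)
    else:
        arr = np.asarray(coeff_matrix, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValidationError("coefficient matrix must have at least one valid row")
    return arr


def summarize(coeff_matrix) -> HeterogeneitySummary:
    """Columnwise μ, quadratic mean, SD (n−1) and SNR of a coefficient matrix."""
    arr = _coef_array(coeff_matrix)
    n = arr.shape[0]
    mu = arr.mean(axis=0)
    qmean = np.sqrt((arr**2).mean(axis=0))
    sigma = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
    sigma[np.ptp(arr, axis=0) == 0] = 0.0  # exactly constant columns
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sigma > 0, np.abs(mu) / np.where(sigma > 0, sigma, 1.0), np.inf)
    return HeterogeneitySummary(
        mu=mu, qmean=qmean, sigma=sigma, snr=snr, n_participants=n
    )


def _stat_columns(arr: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "mu":
        return arr.mean(axis=0)
    if statistic == "qmean":
        return np.sqrt((arr**2).mean(axis=0))
    if statistic == "sigma":
        sd = arr.std(axis=0, ddof=1)
        sd[np.ptp(arr, axis=0) == 0] = 0.0
        return sd
    if statistic == "snr":
        sd = arr.std(axis=0, ddof=1)
        sd[np.ptp(arr, axis=0) == 0] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, np.abs(arr.mean(axis=0)) / np.where(sd > 0, sd, 1.0), np.inf)
    raise ValidationError(f"unknown statistic {statistic!r}; choose from {_STATS}")


def bootstrap_ci(
    coeff_matrix,
    statistic: str = "mu",
    B: int = 100,
    alpha: float = 0.05,
    m_tests: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap percentile CIs of a per-lag population statistic.

    Participants (rows) are resampled with replacement ``B`` times; intervals
    are at the Bonferroni-corrected level ``alpha / m_tests`` where
    ``m_tests`` defaults to the number of lags summarized.
    """
    arr = _coef_array(coeff_matrix)
    if arr.shape[0] < 2:
        raise ValidationError("bootstrap needs at least 2 participants")
    if B < 2:
        warnings.warn("B < 2 gives a degenerate bootstrap interval")
    if m_tests is None:
        m_tests = arr.shape[1]
    level = bonferroni_level(alpha, m_tests)
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    boots = np.empty((B, arr.shape[1]))
    for b in range(B):
        boots[b] = _stat_columns(arr[rng.integers(0, n, size=n)], statistic)
    finite = np.where(np.isfinite(boots), boots, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-inf columns
        lo = np.nanpercentile(finite, 100 * level / 2, axis=0)
        hi = np.nanpercentile(finite, 100 * (1 - level / 2), axis=0)
    return pd.DataFrame(
        {
            "lag": np.arange(arr.shape[1]),
            "estimate": _stat_columns(arr, statistic),
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )


def compare_tasks(
    coeff_matrix_a,
    coeff_matrix_b,
    B: int = 100,
    alpha: float = 0.05,
    m_tests: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-lag differences (A − B) in μ, qmean and SNR with bootstrap CIs.

    The two populations are resampled independently.  Used to contrast the
    reward-free sequential coefficients of two tasks (e.g. operant learning
    vs random sequence generation).
    """
    a = _coef_array(coeff_matrix_a)
    b = _coef_array(coeff_matrix_b)
    if a.shape[1] != b.shape[1]:
        raise ValidationError("coefficient matrices cover different lag ranges")
    if m_tests is None:
        m_tests = a.shape[1]
    level = bonferroni_level(alpha, m_tests)
    rng = np.random.default_rng(seed)
    rows = []
    for stat in ("mu", "qmean", "snr"):
        point = _stat_columns(a, stat) - _stat_columns(b, stat)
        boots = np.empty((B, a.shape[1]))
        for i in range(B):
            ra = a[rng.integers(0, a.shape[0], size=a.shape[0])]
            rb = b[rng.integers(0, b.shape[0], size=b.shape[0])]
            boots[i] = _stat_columns(ra, stat) - _stat_columns(rb, stat)
        finite = np.where(np.isfinite(boots), boots, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(finite, 100 * level / 2, axis=0)
            hi = np.nanpercentile(finite, 100 * (1 - level / 2), axis=0)
        for k in range(a.shape[1]):
            rows.append(
                {
                    "lag": k,
                    "statistic": stat,
                    "difference": point[k],
                    "ci_lo": lo[k],
                    "ci_hi": hi[k],
                }
            )
    return pd.DataFrame(rows)
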