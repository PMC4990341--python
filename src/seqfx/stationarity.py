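"""Discounted-weight stationarity analysis.

Are the sequential-effect coefficients stable over a session?  The scan
refits the lagged logistic model with exponential recency weights — the
training sample ``k`` trials before the test trial gets weight
``(1 − η)·η^k`` — and measures one-step-ahead prediction error from the
middle of the sequence onward, for a grid of discount parameters η.  A
stationary sequence is best predicted by η near 1 (near-uniform weights,
longest effective timescale ``1/(1 − η)``); drifting coefficients favor
smaller η.

The default grid is η = 0 plus 25 values whose recency weights ``1 − η`` are
log-spaced over [10⁻⁶, 1), so the associated timescales span 1 to 10⁶
trials.  Small-η fits have an effective sample size near 1 and cannot
identify ``L + 1`` parameters; they are stabilized with a small ridge
penalty (applied uniformly across the scan and reported in the config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DegenerateDataError, InsufficientDataError, ValidationError
from .logistic import fit_logistic_mle, predict_records
from .sequences import ChoiceSequence, build_lag_design

__all__ = [
    "DiscountConfig",
    "StationarityScan",
    "default_eta_grid",
    "discount_weights",
    "effective_timescale",
    "scan_discounting",
]


def default_eta_grid() -> np.ndarray:
    """η = 0 plus 25 values with recency weight 1 − η log-spaced in [1e-6, 1)."""
    return 1.0 - np.geomspace(1.0, 1e-6, 26)


def discount_weights(n_train: int, eta: float) -> np.ndarray:
    """Exponential recency weights for ``n_train`` training trials.

    Index 0 of the returned vector is the *oldest* training trial; the most
    recent training trial (k = 0) gets weight ``1 − η``.  At η = 0 only the
    most recent trial has weight (0⁰ = 1 by convention); the weights sum to
    ``1 − η^n``.
    """
    if n_train < 1:
        raise ValidationError("n_train must be >= 1")
    if not 0.0 <= eta < 1.0:
        raise ValidationError(f"eta must lie in [0, 1), got {eta}")
    k = np.arange(n_train - 1, -1, -1, dtype=float)
    with np.errstate(divide="ignore"):
        return (1.0 - eta) * np.power(eta, k)


def effective_timescale(eta: float) -> float:
    """Effective memory of the weighting, ``1 / (1 − η)`` trials."""
    if not 0.0 <= eta < 1.0:
        raise ValidationError(f"eta must lie in [0, 1), got {eta}")
    return 1.0 / (1.0 - eta)


@dataclass
class DiscountConfig:
    """Configuration of the stationarity scan.

    ``refit_stride`` trades fidelity for speed: the model is refit every
    ``stride`` test trials and the last fit predicts the trials in between
    (stride 1 reproduces the literal per-trial protocol).  ``test_start`` is
    the 1-based trial at which prediction begins; by default the middle
    sample.  ``ridge`` stabilizes the degenerate small-η fits.
    """

    eta_grid: np.ndarray = field(default_factory=default_eta_grid)
    refit_stride: int = 10
    test_start: int | None = None
    ridge: float = 1e-4

    def __post_init__(self) -> None:
        self.eta_grid = np.asarray(self.eta_grid, dtype=float)
        if self.eta_grid.size == 0:
            raise ValidationError("eta_grid must be non-empty")
        if ((self.eta_grid < 0) | (self.eta_grid >= 1)).any():
            raise ValidationError("all eta values must lie in [0, 1)")
        if self.refit_stride < 1:
            raise ValidationError("refit_stride must be >= 1")


@dataclass
class StationarityScan:
    """Error curve over the discount grid for one sequence."""

    etas: np.ndarray
    errors: np.ndarray  # mean one-step-ahead error per η; NaN if all fits failed
    n_test: int
    best_eta: float
    best_timescale: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eta": self.etas,
                "error_rate": self.errors,
                "timescale": 1.0 / (1.0 - self.etas),
            }
        )


def scan_discounting(
    seq: ChoiceSequence, L: int, config: DiscountConfig | None = None
) -> StationarityScan:
    """One-step-ahead prediction error as a function of the discount η.

    For each η and each test trial ``t`` from ``test_start`` to the end of
    the sequence (refitting every ``refit_stride`` trials), the model is fit
    on all trials before ``t`` with recency weights anchored at ``t``, and
    its hard call for trial ``t`` is scored against the realized choice.
    The best η is the argmin of the mean error (NaN curves from wholly
    degenerate fits are excluded and warned about).
    """
    if config is None:
        config = DiscountConfig()
    n = len(seq)
    if n < 2 * (L + 2):
        raise InsufficientDataError(
            f"sequence of length {n} too short for a stationarity scan at L={L}"
        )
    test_start = config.test_start if config.test_start is not None else n // 2 + 1
    if test_start < L + 2:
        raise ValidationError(f"test_start must be >= L+2={L + 2}")
    design = build_lag_design(seq, L)
    # design row i ↔ trial t = L + 1 + i (1-based)
    first_test_row = test_start - L - 1
    n_rows = design.n_obs
    errors = np.full(config.eta_grid.size, np.nan)
    n_test = n_rows - first_test_row
    for ei, eta in enumerate(config.eta_grid):
        mism = 0
        scored = 0
        for start in range(first_test_row, n_rows, config.refit_stride):
            train = design.subset(np.arange(start))
            w = discount_weights(start, eta)
            try:
                fit = fit_logistic_mle(train, weights=w, ridge=config.ridge)
            except (DegenerateDataError, InsufficientDataError):
                continue
            stop = min(start + config.refit_stride, n_rows)
            block = design.subset(np.arange(start, stop))
            _, _, calls = predict_records(fit.beta_hat, block)
            mism += int((calls != block.responses).sum())
            scored += stop - start
        if scored:
            errors[ei] = mism / scored
    if np.isnan(errors).all():
        raise DegenerateDataError("every discounted fit failed")
    if np.isnan(errors).any():
        warnings.warn("some η values had no successful fit; excluded from argmin")
    # ties (exactly equal error over a plateau of discounts) resolve to the
    # largest η: the longest timescale consistent with the minimal error
    best_idx = int(errors.size - 1 - np.nanargmin(errors[::-1]))
    best_eta = float(config.eta_grid[best_idx])
    return StationarityScan(
        etas=config.eta_grid.copy(),
        errors=errors,
        n_test=n_test,
        best_eta=best_eta,
        best_timescale=effective_timescale(best_eta),
    )
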