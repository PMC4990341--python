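"""Next-symbol predictors and their two cross-validation regimes.

Five models predict choice ``a_t`` from the preceding ``L`` trials:

* ``negative_recency`` — always alternate from the last symbol (parameter
  free, L = 1);
* ``balance`` — predict the minority symbol of the last ``L`` trials
  (parameter free; exact tie falls back to alternation);
* ``logistic`` — hard calls from the fitted lagged logistic model;
* ``hamming_nn`` — nearest neighbor over all training (window → next symbol)
  pairs under Hamming distance, majority vote among ties at the minimal
  distance;
* ``levenshtein`` — as above with unit-cost edit distance.

Two regimes mirror the individual-differences question: *heterogeneous*
(per-participant parameters, contiguous 10-fold CV within participant) and
*homogeneous* (one parameter set for the population, leave-one-participant-
out CV).  Test-trial histories always use the participant's true preceding
choices.  Prediction-error rates are averaged across folds, then across
participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from ._errors import RegimeError, ValidationError
from .logistic import fit_logistic_mle, predict_records
from .sequences import (
    ChoiceSequence,
    build_lag_design,
    group_by_participant,
    stack_designs,
)

__all__ = [
    "MODEL_NAMES",
    "PARAMETER_FREE",
    "PredictorResult",
    "predict_negative_recency",
    "predict_balance",
    "predict_hamming_nn",
    "predict_levenshtein",
    "evaluate_heterogeneous",
    "evaluate_homogeneous",
    "select_memory_length",
    "calibration_curve",
]

MODEL_NAMES = ("negative_recency", "balance", "levenshtein", "logistic", "hamming_nn")
PARAMETER_FREE = frozenset({"negative_recency", "balance"})

_MAX_NN_L = 20  # pattern tables are indexed by 2^L codes


# ---------------------------------------------------------------------------
# single-call predictors


def predict_negative_recency(history) -> int:
    """Alternate from the previous symbol: returns ``1 - a_{t-1}``."""
    history = np.asarray(history)
    if history.size < 1:
        raise ValidationError("history must contain at least one trial")
    return int(1 - history[-1])


def predict_balance(history, L: int) -> int:
    """Minority symbol of the last ``L`` trials; ties alternate from last."""
    if L < 1:
        raise ValidationError("L must be >= 1")
    history = np.asarray(history)
    if history.size < L:
        raise ValidationError(f"history shorter than L={L}")
    window = history[-L:]
    ones = int(window.sum())
    if 2 * ones > L:
        return 0
    if 2 * ones < L:
        return 1
    return predict_negative_recency(history)


# ---------------------------------------------------------------------------
# nearest-neighbor machinery: windows are encoded as integers in [0, 2^L)

def _encode_windows(choices: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """All (window code, next symbol) pairs of a sequence.

    The window before trial ``t`` (0-based ``t = L..N-1``) is
    ``a_{t-L}..a_{t-1}``, encoded big-endian (most recent symbol = lowest bit).
    """
    n = choices.size
    if n <= L:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    a = choices.astype(np.int64)
    codes = np.zeros(n - L, dtype=np.int64)
    for j in range(L):
        # symbol j+1 trials back contributes bit j
        codes |= a[L - 1 - j : n - 1 - j] << j
    return codes, choices[L:]


class _NNTable:
    """Vote table of training (window → next symbol) pairs, by window code."""

    def __init__(self, L: int):
        if not 1 <= L <= _MAX_NN_L:
            raise ValidationError(f"nearest-neighbor L must be in [1, {_MAX_NN_L}]")
        self.L = L
        self.n1 = np.zeros(2**L, dtype=np.int64)
        self.n0 = np.zeros(2**L, dtype=np.int64)

    def add(self, codes: np.ndarray, nxt: np.ndarray) -> None:
        self.n1 += np.bincount(codes[nxt == 1], minlength=2**self.L)
        self.n0 += np.bincount(codes[nxt == 0], minlength=2**self.L)

    @property
    def n_pairs(self) -> int:
        return int(self.n1.sum() + self.n0.sum())

    def present(self) -> np.ndarray:
        return np.flatnonzero(self.n1 + self.n0)


def _code_to_string(code: int, L: int) -> str:
    return format(code, f"0{L}b")


@lru_cache(maxsize=32)
def _levenshtein_table(L: int) -> np.ndarray:
    """Edit-distance matrix between all pairs of length-L binary strings."""
    strings = [_code_to_string(c, L) for c in range(2**L)]
    D = np.zeros((2**L, 2**L), dtype=np.int16)
    for i, si in enumerate(strings):
        for j in range(i + 1, 2**L):
            d = edlib.align(si, strings[j], mode="NW", task="distance")["editDistance"]
            D[i, j] = D[j, i] = d
    return D


def _nn_predict(
    table: _NNTable,
    query_codes: np.ndarray,
    last_symbols: np.ndarray,
    metric: str,
) -> np.ndarray:
    """Hard calls for query windows under a nearest-neighbor vote.

    Among training patterns at minimal distance, the majority next symbol
    wins; an exact vote tie alternates from the last symbol of the window.
    """
    if table.n_pairs == 0:
        raise RegimeError("nearest-neighbor training set is empty")
    present = table.present()
    if metric == "hamming":
        dist = np.bitwise_count(query_codes[:, None] ^ present[None, :])
    elif metric == "levenshtein":
        dist = _levenshtein_table(table.L)[np.ix_(query_codes, present)]
    else:  # pragma: no cover
        raise ValidationError(f"unknown metric {metric!r}")
    dmin = dist.min(axis=1)
    at_min = dist == dmin[:, None]
    votes1 = at_min @ table.n1[present]
    votes0 = at_min @ table.n0[present]
    calls = np.where(votes1 > votes0, 1, 0).astype(np.int8)
    ties = votes1 == votes0
    calls[ties] = 1 - last_symbols[ties]
    return calls


def predict_hamming_nn(history, training_set, L: int) -> int:
    """Hamming nearest-neighbor call for one query window.

    ``training_set`` is an iterable of ``(window, next_symbol)`` pairs, each
    window a length-L 0/1 sequence ordered oldest-first.
    """
    return _predict_nn_single(history, training_set, L, "hamming")


def predict_levenshtein(history, training_set, L: int) -> int:
    """Edit-distance nearest-neighbor call for one query window."""
    return _predict_nn_single(history, training_set, L, "levenshtein")


def _predict_nn_single(history, training_set, L, metric) -> int:
    history = np.asarray(history)
    if history.size < L:
        raise ValidationError(f"history shorter than L={L}")
    table = _NNTable(L)
    pairs = list(training_set)
    if not pairs:
        raise RegimeError("nearest-neighbor training set is empty")
    for window, nxt in pairs:
        window = np.asarray(window, dtype=np.int64)
        if window.size != L:
            raise ValidationError("training window length != L")
        code = int((window[::-1] << np.arange(L)).sum())
        if nxt == 1:
            table.n1[code] += 1
        else:
            table.n0[code] += 1
    w = history[-L:].astype(np.int64)
    qcode = int((w[::-1] << np.arange(L)).sum())
    return int(
        _nn_predict(
            table,
            np.array([qcode]),
            np.array([history[-1]], dtype=np.int8),
            metric,
        )[0]
    )


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class PredictorResult:
    """Cross-validated prediction-error summary for one model and regime."""

    model_name: str
    regime: str
    L_used: int
    error_rate: float
    error_ci: tuple[float, float]
    per_participant: pd.Series
    records: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValidationError("error_rate must lie in [0, 1]")


def _check_model(model: str) -> None:
    if model not in MODEL_NAMES:
        raise ValidationError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def _model_calls(
    model: str,
    L: int,
    train_seqs_rows: list[tuple[ChoiceSequence, np.ndarray]],
    test_seq: ChoiceSequence,
    test_rows: np.ndarray,
):
    """Predict the test rows of one sequence.

    ``train_seqs_rows`` lists (sequence, design-row indices) pairs supplying
    training material; row ``i`` of a sequence's design is trial ``L + i``
    (0-based).  Returns ``(calls, probs)`` with ``probs`` NaN for models that
    emit hard calls only.
    """
    a_test = test_seq.choices
    probs = np.full(test_rows.size, np.nan)

    if model == "negative_recency":
        calls = 1 - a_test[test_rows + L - 1]
        return calls.astype(np.int8), probs

    if model == "balance":
        calls = np.array(
            [predict_balance(a_test[: L + t], L) for t in test_rows], dtype=np.int8
        )
        return calls, probs

    if model == "logistic":
        design_parts = [
            build_lag_design(seq, L).subset(rows)
            for seq, rows in train_seqs_rows
            if rows.size
        ]
        fit = fit_logistic_mle(stack_designs(design_parts))
        test_design = build_lag_design(test_seq, L).subset(test_rows)
        _, p, calls = predict_records(fit.beta_hat, test_design)
        return calls, p

    # nearest-neighbor models
    metric = "hamming" if model == "hamming_nn" else "levenshtein"
    table = _NNTable(L)
    for seq, rows in train_seqs_rows:
        codes, nxt = _encode_windows(seq.choices, L)
        table.add(codes[rows], nxt[rows])
    q_codes, _ = _encode_windows(a_test, L)
    q_codes = q_codes[test_rows]
    last = a_test[test_rows + L - 1].astype(np.int8)
    calls = _nn_predict(table, q_codes, last, metric)
    return calls, probs


def _contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    return [f for f in np.array_split(np.arange(n), k) if f.size]


def _result(
    model: str,
    regime: str,
    L: int,
    per_participant: dict[str, float],
    records: list[pd.DataFrame],
) -> PredictorResult:
    per = pd.Series(per_participant, name="error").sort_index()
    err = float(per.mean())
    if len(per) > 1:
        sem = per.std(ddof=1) / np.sqrt(len(per))
        t = stats.t.ppf(0.975, len(per) - 1)
        ci = (max(0.0, err - t * sem), min(1.0, err + t * sem))
    else:
        ci = (err, err)
    rec = pd.concat(records, ignore_index=True) if records else None
    return PredictorResult(
        model_name=model,
        regime=regime,
        L_used=L,
        error_rate=err,
        error_ci=ci,
        per_participant=per,
        records=rec,
    )


def evaluate_heterogeneous(
    model: str,
    seqs: Iterable[ChoiceSequence],
    L: int,
    n_folds: int = 10,
    collect_records: bool = False,
    shuffle_folds: bool = False,
    seed: int | None = None,
) -> PredictorResult:
    """Within-participant cross-validation with per-participant parameters.

    Each participant's design rows are split into ``n_folds`` contiguous
    blocks (contiguity preserves the sequential dependence being modeled;
    set ``shuffle_folds=True`` for random folds).  Parameters are fit on the
    other folds, errors measured on the held-out fold, then averaged across
    folds and participants.  Parameter-free models skip fitting but use the
    same test trials.
    """
    _check_model(model)
    groups = group_by_participant(list(seqs))
    rng = np.random.default_rng(seed)
    per: dict[str, float] = {}
    records: list[pd.DataFrame] = []
    for pid, blocks in groups.items():
        fold_errors: list[float] = []
        try:
            n_rows_per_block = [len(b) - L for b in blocks]
            if min(n_rows_per_block) < n_folds:
                raise ValidationError(
                    f"participant {pid!r}: sequence too short for "
                    f"{n_folds}-fold CV at L={L}"
                )
        except ValidationError as exc:
            warnings.warn(str(exc) + " — skipped")
            continue
        for fold in range(n_folds):
            mism = 0
            n_test = 0
            for b_idx, seq in enumerate(blocks):
                rows = np.arange(n_rows_per_block[b_idx])
                if shuffle_folds:
                    rows = rng.permutation(rows)
                folds = _contiguous_folds(rows.size, n_folds)
                test_rows = np.sort(rows[folds[fold]])
                train_mask = np.ones(rows.size, dtype=bool)
                train_mask[folds[fold]] = False
                train_rows = np.sort(rows[train_mask])
                train_material = [
                    (blk, np.arange(n_rows_per_block[j]) if j != b_idx else train_rows)
                    for j, blk in enumerate(blocks)
                ]
                calls, probs = _model_calls(
                    model, L, train_material, seq, test_rows
                )
                outcome = seq.choices[test_rows + L]
                mism += int((calls != outcome).sum())
                n_test += test_rows.size
                if collect_records:
                    records.append(
                        pd.DataFrame(
                            {
                                "participant": pid,
                                "trial": test_rows + L + 1,
                                "p_heads": probs,
                                "call": calls,
                                "outcome": outcome,
                            }
                        )
                    )
            fold_errors.append(mism / n_test)
        per[pid] = float(np.mean(fold_errors))
    if not per:
        raise RegimeError("no participant had enough trials to evaluate")
    return _result(model, "heterogeneous", L, per, records)


def evaluate_homogeneous(
    model: str,
    seqs: Iterable[ChoiceSequence],
    L: int,
    collect_records: bool = False,
) -> PredictorResult:
    """Leave-one-participant-out cross-validation with shared parameters.

    For each held-out participant one parameter set is fit on all other
    participants (stacked designs / pooled pattern tables) and evaluated on
    every eligible trial of the held-out participant.  Parameter-free models
    give the same result as in the heterogeneous regime.
    """
    _check_model(model)
    groups = group_by_participant(list(seqs))
    if len(groups) < 2:
        raise RegimeError("homogeneous regime needs at least 2 participants")
    per: dict[str, float] = {}
    records: list[pd.DataFrame] = []
    pids = list(groups)
    for pid in pids:
        train_material = [
            (blk, np.arange(len(blk) - L))
            for other in pids
            if other != pid
            for blk in groups[other]
            if len(blk) > L
        ]
        mism = 0
        n_test = 0
        for seq in groups[pid]:
            if len(seq) <= L:
                continue
            test_rows = np.arange(len(seq) - L)
            calls, probs = _model_calls(model, L, train_material, seq, test_rows)
            outcome = seq.choices[test_rows + L]
            mism += int((calls != outcome).sum())
            n_test += test_rows.size
            if collect_records:
                records.append(
                    pd.DataFrame(
                        {
                            "participant": pid,
                            "trial": test_rows + L + 1,
                            "p_heads": probs,
                            "call": calls,
                            "outcome": outcome,
                        }
                    )
                )
        if n_test:
            per[pid] = mism / n_test
    return _result(model, "homogeneous", L, per, records)


def select_memory_length(
    model: str,
    seqs: Iterable[ChoiceSequence],
    regime: str,
    L_grid: Sequence[int],
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the memory length minimizing cross-validated error.

    Returns ``(best_L, curve)`` where ``curve`` has one row per ``L``; ties
    go to the smallest ``L``.
    """
    L_grid = sorted(set(int(x) for x in L_grid))
    if not L_grid:
        raise ValidationError("L_grid must be non-empty")
    seqs = list(seqs)
    rows = []
    for L in L_grid:
        if regime == "heterogeneous":
            res = evaluate_heterogeneous(model, seqs, L, **kwargs)
        elif regime == "homogeneous":
            res = evaluate_homogeneous(model, seqs, L, **kwargs)
        else:
            raise ValidationError(f"unknown regime {regime!r}")
        rows.append({"L": L, "error_rate": res.error_rate})
    curve = pd.DataFrame(rows)
    best_L = int(curve.loc[curve["error_rate"].idxmin(), "L"])
    return best_L, curve


def calibration_curve(
    predicted_probs, outcomes, n_bins: int = 20
) -> tuple[pd.DataFrame, float]:
    """Reliability curve over equally populated probability bins.

    Observations are sorted by predicted probability and split into
    ``n_bins`` quantile bins; each bin contributes its mean predicted
    probability and the empirical frequency of outcome 1.  Returns the bin
    table and the Pearson correlation between the two columns — near 1 when
    the link function matches the data-generating nonlinearity.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predicted_probs and outcomes must be equal-length 1-D")
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("predicted probabilities must lie in (0, 1)")
    if p.size < n_bins:
        warnings.warn(
            f"only {p.size} points for {n_bins} bins; reducing to {p.size}"
        )
        n_bins = p.size
    order = np.argsort(p, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        rows.append(
            {
                "p_predicted": float(p[chunk].mean()),
                "p_empirical": float(y[chunk].mean()),
                "n": int(chunk.size),
            }
        )
    table = pd.DataFrame(rows)
    if table["p_predicted"].nunique() < 2:
        r = float("nan")  # constant predictions: correlation undefined
    else:
        r = float(stats.pearsonr(table["p_predicted"], table["p_empirical"])[0])
    return table, r
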