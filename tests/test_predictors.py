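"""Next-symbol predictors, CV regimes, memory-length selection, calibration."""

import numpy as np
import pytest

from seqfx import (
    ChoiceSequence,
    PopulationSpec,
    bayes_error_lag1,
    calibration_curve,
    evaluate_heterogeneous,
    evaluate_homogeneous,
    generate_fair_coin,
    generate_population,
    predict_balance,
    predict_negative_recency,
    select_memory_length,
)
from seqfx._errors import RegimeError, ValidationError
from seqfx.predictors import predict_hamming_nn, predict_levenshtein


def test_negative_recency_rule():
    assert predict_negative_recency([0, 1]) == 0
    assert predict_negative_recency([1, 0]) == 1
    with pytest.raises(ValidationError):
        predict_negative_recency([])


def test_negative_recency_perfect_on_alternation():
    seqs = [ChoiceSequence("p", [0, 1] * 50)]
    res = evaluate_heterogeneous("negative_recency", seqs, 1)
    assert res.error_rate == 0.0


@pytest.mark.parametrize(
    "window,L,expected",
    [
        ([1, 1, 1, 1, 0, 0, 0], 7, 0),
        ([0, 0, 0, 0, 0, 0, 0], 7, 1),
        ([1, 1, 0, 0], 4, 1),  # tie, last symbol 0 -> alternate to 1
    ],
)
def test_balance_rule(window, L, expected):
    assert predict_balance(window, L) == expected


def test_hamming_nn_enumerated_example():
    """Training pairs from 0,1,0,1,0,1,0,1 at L=2: query (0,1) -> 0."""
    seq = [0, 1, 0, 1, 0, 1, 0, 1]
    pairs = [(seq[i : i + 2], seq[i + 2]) for i in range(6)]
    assert predict_hamming_nn([0, 1], pairs, 2) == 0
    assert predict_levenshtein([0, 1], pairs, 2) == 0


def test_nn_distance_zero_unanimity():
    pairs = [([1, 0, 1], 1), ([1, 0, 1], 1), ([0, 0, 0], 0)]
    assert predict_hamming_nn([1, 0, 1], pairs, 3) == 1


def test_nn_empty_training_set():
    with pytest.raises(RegimeError):
        predict_hamming_nn([1, 0], [], 2)


def test_levenshtein_le_hamming_on_equal_length(rng):
    """Substitutions alone realize the Hamming distance."""
    import edlib

    for _ in range(50):
        a = "".join(map(str, rng.integers(0, 2, 8)))
        b = "".join(map(str, rng.integers(0, 2, 8)))
        lev = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        ham = sum(x != y for x, y in zip(a, b))
        assert lev <= ham


def test_fair_coin_unpredictable():
    seqs = generate_fair_coin(4000, 4, seed=51)
    for model in ("negative_recency", "hamming_nn", "logistic"):
        res = evaluate_heterogeneous(model, seqs, 2)
        assert abs(res.error_rate - 0.5) < 0.05


@pytest.fixture(scope="module")
def lag1_population():
    spec = PopulationSpec(
        n_participants=12, n_trials=1000, L_gen=1,
        beta_mean=[0, 0], beta_sd=[0, 1], seed=52,
    )
    return generate_population(spec)


def test_regime_ordering_on_heterogeneous_population(lag1_population):
    """Individual parameters beat shared ones when effects are idiosyncratic.

    With a mean-zero heterogeneous lag-1 effect the pooled model carries no
    usable signal: leaving one participant out even anti-correlates the
    pooled slope with that participant's own effect, so the homogeneous
    error is at or above chance while the heterogeneous error approaches the
    generator's irreducible error.
    """
    seqs, truth = lag1_population
    het = evaluate_heterogeneous("logistic", seqs, 1)
    hom = evaluate_homogeneous("logistic", seqs, 1)
    bayes = np.mean([bayes_error_lag1(b) for b in truth.to_numpy()])
    assert het.error_rate < 0.5 - 0.05
    assert het.error_rate < hom.error_rate - 0.05
    assert hom.error_rate > 0.45
    assert het.error_rate == pytest.approx(bayes, abs=0.03)


def test_parameter_free_models_identical_across_regimes(lag1_population):
    seqs, _ = lag1_population
    het = evaluate_heterogeneous("negative_recency", seqs, 1)
    hom = evaluate_homogeneous("negative_recency", seqs, 1)
    # same rule, same test trials in the homogeneous regime (all rows)
    assert abs(het.error_rate - hom.error_rate) < 0.01


def test_homogeneous_regime_needs_two_participants():
    seqs = generate_fair_coin(100, 1, seed=53)
    with pytest.raises(RegimeError):
        evaluate_homogeneous("logistic", seqs, 1)


def test_error_rate_is_one_minus_accuracy(lag1_population):
    seqs, _ = lag1_population
    res = evaluate_heterogeneous("logistic", seqs, 1, collect_records=True)
    acc = (res.records["call"] == res.records["outcome"]).mean()
    per_trial_err = 1.0 - acc
    # fold/participant averaging differs from trial pooling only slightly
    assert res.error_rate == pytest.approx(per_trial_err, abs=0.01)
    assert 0.0 <= res.error_rate <= 1.0


def test_select_memory_length_recovers_horizon():
    spec = PopulationSpec(
        n_participants=8, n_trials=1500, L_gen=3,
        beta_mean=[0, 0, 0, -1.2], beta_sd=[0, 0, 0, 0.2], seed=54,
    )
    seqs, _ = generate_population(spec)
    best_L, curve = select_memory_length(
        "logistic", seqs, "heterogeneous", range(1, 6)
    )
    assert best_L >= 3
    errs = curve.set_index("L")["error_rate"]
    assert errs.loc[3] < errs.loc[1] - 0.05  # the true horizon helps
    assert abs(errs.loc[5] - errs.loc[3]) < 0.02  # flat beyond the horizon


def test_select_memory_length_singleton_grid():
    seqs = generate_fair_coin(300, 3, seed=55)
    best_L, curve = select_memory_length("balance", seqs, "homogeneous", [1])
    assert best_L == 1 and len(curve) == 1


def test_calibration_well_calibrated(rng):
    p = rng.uniform(0.05, 0.95, 10_000)
    y = rng.random(10_000) < p
    table, r = calibration_curve(p, y.astype(int), n_bins=20)
    assert len(table) == 20
    assert r > 0.95
    assert np.abs(table["p_predicted"] - table["p_empirical"]).max() < 0.1


def test_calibration_constant_predictions(rng):
    p = np.full(100, 0.5)
    y = rng.integers(0, 2, 100)
    table, r = calibration_curve(p, y, n_bins=20)
    assert np.isnan(r)  # single effective bin, correlation undefined


def test_calibration_fewer_points_than_bins(rng):
    with pytest.warns(UserWarning):
        table, _ = calibration_curve(rng.uniform(0.1, 0.9, 10), rng.integers(0, 2, 10))
    assert len(table) == 10


def test_logistic_predictions_are_calibrated(lag1_population):
    seqs, _ = lag1_population
    res = evaluate_heterogeneous("logistic", seqs, 1, collect_records=True)
    rec = res.records.dropna(subset=["p_heads"])
    table, r = calibration_curve(rec["p_heads"], rec["outcome"], n_bins=20)
    assert r > 0.95
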