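"""Logistic core: probability rule, MLE, oracles, multiple-comparison level."""

import numpy as np
import pytest

from seqfx import (
    ChoiceSequence,
    bonferroni_level,
    build_lag_design,
    choice_probability,
    fit_logistic_mle,
    generate_fair_coin,
    generate_logistic_agent,
    grid_search_mle,
    predict_records,
)
from seqfx._errors import DegenerateDataError, ValidationError


@pytest.mark.parametrize(
    "dq,expected",
    [(0.0, 0.5), (1.0, 1 / (1 + np.exp(-1))), (700.0, 1.0), (-700.0, 0.0)],
)
def test_choice_probability_values(dq, expected):
    assert choice_probability(dq) == pytest.approx(expected, abs=1e-12)


def test_choice_probability_rejects_nan():
    with pytest.raises(ValidationError):
        choice_probability(float("nan"))


@pytest.mark.parametrize(
    "alpha,m,expected", [(0.05, 10, 0.005), (0.05, 30, 0.05 / 30), (0.05, 1, 0.05)]
)
def test_bonferroni_level(alpha, m, expected):
    assert bonferroni_level(alpha, m) == pytest.approx(expected)


def test_mle_recovers_generative_truth():
    beta = np.array([0.3, -0.8])
    seq = generate_logistic_agent(beta, 10_000, seed=21)
    fit = fit_logistic_mle(build_lag_design(seq, 1))
    assert fit.converged
    assert (np.abs(fit.beta_hat - beta) < 3 * fit.se).all()
    assert (fit.ci_lo <= fit.beta_hat).all() and (fit.beta_hat <= fit.ci_hi).all()


def test_fair_coin_coefficients_not_significant():
    """At the Bonferroni level 0.05/10, fair sequences show no effects."""
    level = bonferroni_level(0.05, 10)
    n_sig = 0
    for seed in (31, 32, 33):
        seq = generate_fair_coin(10_000, 1, seed=seed)[0]
        fit = fit_logistic_mle(build_lag_design(seq, 10), ci_alpha=level)
        n_sig += int((fit.wald_p < level).sum())
    assert n_sig <= 1  # 33 tests at level 0.005: more than one hit is unlikely


def test_uniform_weights_equal_unweighted():
    seq = generate_logistic_agent([0.1, -0.5], 2000, seed=22)
    d = build_lag_design(seq, 1)
    f0 = fit_logistic_mle(d)
    fc = fit_logistic_mle(d, weights=np.full(d.n_obs, 3.7))
    np.testing.assert_allclose(fc.beta_hat, f0.beta_hat, atol=1e-6)


def test_loglik_at_mle_beats_null():
    seq = generate_logistic_agent([0.0, -0.6], 500, seed=23)
    d = build_lag_design(seq, 1)
    fit = fit_logistic_mle(d)
    # null model log-likelihood: all p = 0.5
    ll0 = d.n_obs * np.log(0.5)
    assert fit.loglik >= ll0


def test_grid_search_oracle_agreement():
    """Newton MLE matches exhaustive likelihood maximization on a grid."""
    rng = np.random.default_rng(24)
    for _ in range(5):
        seq = ChoiceSequence("p", rng.integers(0, 2, 30))
        d = build_lag_design(seq, 1)
        try:
            fit = fit_logistic_mle(d)
        except DegenerateDataError:
            continue
        ref = grid_search_mle(d, step=0.01, bound=3.0)
        assert np.abs(fit.beta_hat - ref).max() <= 0.01 + 1e-9


def test_statsmodels_cross_check():
    """Independent GLM implementation agrees on coefficients and SEs."""
    import statsmodels.api as sm

    seq = generate_logistic_agent([0.2, -0.7, 0.3], 3000, seed=25)
    d = build_lag_design(seq, 2)
    fit = fit_logistic_mle(d)
    ref = sm.GLM(d.responses, d.matrix(), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.beta_hat, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_separation_capped_not_crashed():
    # strictly alternating sequence: beta_1 -> -inf under plain ML
    seq = ChoiceSequence("p", [0, 1] * 20)
    fit = fit_logistic_mle(build_lag_design(seq, 1))
    assert not fit.converged
    assert np.abs(fit.beta_hat).max() <= 20.0 + 1e-9


def test_degenerate_constant_responses():
    with pytest.raises(DegenerateDataError):
        fit_logistic_mle(build_lag_design(ChoiceSequence("p", [1] * 30), 1))


def test_hard_call_tie_predicts_one():
    d = build_lag_design(ChoiceSequence("p", [0, 1, 0, 1, 0]), 1)
    _, p, calls = predict_records(np.zeros(2), d)
    assert (p == 0.5).all() and (calls == 1).all()


def test_recovery_unbiased_over_agents():
    """Mean signed estimation error is within Monte-Carlo error of zero."""
    beta = np.array([0.3, -0.8])
    errs = []
    for seed in range(60):
        seq = generate_logistic_agent(beta, 1000, seed=1000 + seed)
        fit = fit_logistic_mle(build_lag_design(seq, 1))
        errs.append(fit.beta_hat - beta)
    errs = np.array(errs)
    bias = errs.mean(axis=0)
    sem = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
    assert (np.abs(bias) < 3 * sem + 1e-3).all()
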