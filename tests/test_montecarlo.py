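"""Monte-Carlo engine: sampling correctness, determinism, oracle agreement."""

import numpy as np
import pytest

from excess_success import (
    ConditionSpec,
    DegenerateSampleError,
    FixtureConfig,
    InsufficientRepsError,
    InvalidDesignError,
    MeasureModel,
    Requirement,
    Sign,
    StudyDesign,
    SuccessCriterion,
    TestSpec,
    estimate_success,
    make_random_design,
    power_two_sample,
    prob_outcome_for_design,
    sample_condition,
    simulate_once,
)


def test_sample_condition_recovers_population_moments():
    model = MeasureModel(("m1", "m2"), [10.0, 20.0], [1.0, 3.0], [[1.0, 0.9], [0.9, 1.0]])
    cond = ConditionSpec("a", 100_000, model)
    frame = sample_condition(cond, np.random.default_rng(7))
    # means within 4 standard errors
    assert frame["m1"].mean() == pytest.approx(10.0, abs=4 * 1.0 / np.sqrt(100_000))
    assert frame["m2"].mean() == pytest.approx(20.0, abs=4 * 3.0 / np.sqrt(100_000))
    assert frame["m1"].std() == pytest.approx(1.0, rel=0.02)
    # Fisher-z SE for r=0.9 at n=1e5 is ~0.0006 on z; +-0.01 on r is generous
    assert frame["m1"].corr(frame["m2"]) == pytest.approx(0.9, abs=0.01)


def test_sample_condition_deterministic_given_stream_state():
    model = MeasureModel(("m1",), [0.0], [1.0], [[1.0]])
    cond = ConditionSpec("a", 5, model)
    a = sample_condition(cond, np.random.default_rng(3))
    b = sample_condition(cond, np.random.default_rng(3))
    assert a.equals(b)


def test_estimate_is_bitwise_deterministic(null_two_condition, directed_null_criterion):
    a = estimate_success(null_two_condition, directed_null_criterion, reps=5_000, seed=11)
    b = estimate_success(null_two_condition, directed_null_criterion, reps=5_000, seed=11)
    assert a == b


def test_different_seeds_stay_within_monte_carlo_noise(null_two_condition):
    crit = SuccessCriterion((TestSpec.between("t1", "a", "b", "m1", Requirement.NON_SIGNIFICANT),))
    a = estimate_success(null_two_condition, crit, reps=20_000, seed=1)
    b = estimate_success(null_two_condition, crit, reps=20_000, seed=2)
    assert a.p_hat != b.p_hat or a.per_test_rates != b.per_test_rates
    assert abs(a.p_hat - b.p_hat) < 4 * max(a.mc_se, b.mc_se)


def test_null_rejection_rates(null_two_condition, directed_null_criterion):
    est = estimate_success(null_two_condition, directed_null_criterion, reps=40_000, seed=5)
    # direction enforced: only the expected tail counts -> alpha/2
    assert est.p_hat == pytest.approx(0.025, abs=3 * est.mc_se + 1e-9)
    loose = estimate_success(
        null_two_condition, directed_null_criterion, reps=40_000, seed=5,
        enforce_direction=False,
    )
    assert loose.p_hat == pytest.approx(0.05, abs=3 * loose.mc_se)


def test_conjunction_bound_holds_exactly(priming_study):
    design, criterion = priming_study
    est = estimate_success(design, criterion, reps=5_000, seed=9)
    assert est.p_hat <= min(est.per_test_rates.values()) + 1e-15
    assert 0.0 <= est.mc_se <= 0.5 / np.sqrt(est.reps)
    assert set(est.per_test_rates) == {t.test_id for t in criterion.tests}


def test_independent_tests_multiply(null_two_condition):
    """Two significance requirements on disjoint condition pairs: joint rate
    equals the product of analytic in-direction powers."""
    m0 = MeasureModel(("m1",), [0.0], [1.0], [[1.0]])
    m1 = MeasureModel(("m1",), [0.7], [1.0], [[1.0]])
    design = StudyDesign(
        "two-pairs",
        (
            ConditionSpec("a", 25, m1),
            ConditionSpec("b", 25, m0),
            ConditionSpec("c", 30, m1),
            ConditionSpec("d", 30, m0),
        ),
    )
    crit = SuccessCriterion(
        (
            TestSpec.between("t1", "a", "b", "m1", Requirement.SIGNIFICANT_IN_DIRECTION, Sign.POSITIVE),
            TestSpec.between("t2", "c", "d", "m1", Requirement.SIGNIFICANT_IN_DIRECTION, Sign.POSITIVE),
        )
    )
    est = estimate_success(design, crit, reps=40_000, seed=21)
    p1 = power_two_sample(0.7, 25, 25).p_sig_in_direction
    p2 = power_two_sample(0.7, 30, 30).p_sig_in_direction
    assert est.p_hat == pytest.approx(p1 * p2, abs=3 * est.mc_se)


def test_single_test_rates_match_analytic_oracle_over_random_designs():
    """Cross-module oracle: MC marginal rate vs noncentral-t probability,
    over a grid of random homoscedastic designs."""
    misses = 0
    for seed in range(12):
        design, criterion = make_random_design(
            FixtureConfig(seed=seed, n_conditions=3, n_measures=2, n_tests=1)
        )
        spec = criterion.tests[0]
        est = estimate_success(design, criterion, reps=10_000, seed=1000 + seed)
        analytic = prob_outcome_for_design(design, spec)
        tol = 3 * max(est.mc_se, np.sqrt(analytic * (1 - analytic) / est.reps))
        if abs(est.p_hat - analytic) > tol:
            misses += 1
    assert misses == 0


def test_simulate_once_agrees_with_estimate_semantics(priming_study):
    design, criterion = priming_study
    results, success = simulate_once(design, criterion, np.random.default_rng(2))
    assert len(results) == len(criterion.tests)
    assert all(0.0 <= r.p_value <= 1.0 and r.df > 0 for r in results)
    assert isinstance(success, bool)


def test_zero_sd_design_is_rejected_before_simulation():
    model = MeasureModel(("m1",), [0.0], [0.0], [[1.0]])
    design = StudyDesign("bad", (ConditionSpec("a", 5, model), ConditionSpec("b", 5, model)))
    crit = SuccessCriterion((TestSpec.between("t", "a", "b", "m1", Requirement.NON_SIGNIFICANT),))
    with pytest.raises(InvalidDesignError):
        estimate_success(design, crit, reps=200, seed=0)
    # bypassing validation, the degenerate draw itself aborts the estimate
    with pytest.raises(DegenerateSampleError):
        estimate_success(design, crit, reps=200, seed=0, validate=False)


def test_too_few_reps_rejected(null_two_condition, directed_null_criterion):
    with pytest.raises(InsufficientRepsError):
        estimate_success(null_two_condition, directed_null_criterion, reps=99, seed=0)
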