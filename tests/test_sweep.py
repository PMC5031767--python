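"""Sample-size sweeps, optimum detection, and multi-study aggregation."""

import math

import numpy as np
import pytest

from excess_success import (
    ConditionSpec,
    MeasureModel,
    Requirement,
    Sign,
    StudyDesign,
    SuccessCriterion,
    SuccessEstimate,
    SweepResult,
    TestSpec,
    aggregate_product,
    find_optimum,
    power_two_sample,
    success_curve,
)


def _sig_only_design():
    m0 = MeasureModel(("m1",), [0.0], [1.0], [[1.0]])
    m1 = MeasureModel(("m1",), [0.8], [1.0], [[1.0]])
    design = StudyDesign("s", (ConditionSpec("a", 10, m1), ConditionSpec("b", 10, m0)))
    crit = SuccessCriterion(
        (TestSpec.between("t1", "a", "b", "m1", Requirement.SIGNIFICANT_IN_DIRECTION, Sign.POSITIVE),)
    )
    return design, crit


def test_significance_only_curve_rises_to_one():
    design, crit = _sig_only_design()
    sweep = success_curve(design, crit, n_grid=[5, 10, 20, 40, 80], reps_per_point=4_000, seed=3)
    p = [e.p_hat for e in sweep.estimates]
    se = [e.mc_se for e in sweep.estimates]
    # nondecreasing within Monte-Carlo noise, and ~1 at large n
    assert all(b >= a - 3 * (sa + sb) for a, b, sa, sb in zip(p, p[1:], se, se[1:]))
    assert p[-1] > 0.99
    assert sweep.n_star == 80 or sweep.p_max == pytest.approx(1.0, abs=0.01)


def test_curve_records_per_test_marginals(priming_study):
    design, criterion = priming_study
    sweep = success_curve(design, criterion, n_grid=[10, 20], reps_per_point=1_000, seed=0)
    frame = sweep.to_frame()
    marginal_cols = [c for c in frame.columns if c.startswith("marginal_")]
    assert len(marginal_cols) == len(criterion.tests)
    assert list(frame["n"]) == [10, 20]


def test_grid_must_be_increasing(priming_study):
    design, criterion = priming_study
    with pytest.raises(ValueError):
        success_curve(design, criterion, n_grid=[10, 10], reps_per_point=1_000)
    with pytest.raises(ValueError):
        success_curve(design, criterion, n_grid=[1, 5], reps_per_point=1_000)
    with pytest.raises(ValueError):
        success_curve(design, criterion, n_grid=[], reps_per_point=1_000)


def _fake_sweep(pairs):
    ests = tuple(
        SuccessEstimate(p, 1000, math.sqrt(p * (1 - p) / 1000), {}, 0) for _, p in pairs
    )
    grid = tuple(n for n, _ in pairs)
    n_star, p_max = max(zip(grid, (e.p_hat for e in ests)), key=lambda t: (t[1], -t[0]))
    return SweepResult(grid, ests, n_star, p_max)


def test_find_optimum_monotone_single_point_and_ties():
    assert find_optimum(_fake_sweep([(5, 0.1), (10, 0.4), (20, 0.9)])) == (20, 0.9)
    assert find_optimum(_fake_sweep([(7, 0.33)])) == (7, 0.33)
    # ties break toward the smaller (cheaper) n
    assert find_optimum(_fake_sweep([(5, 0.5), (10, 0.5), (20, 0.2)])) == (5, 0.5)


def test_sweep_result_invariant(priming_study):
    design, criterion = priming_study
    sweep = success_curve(design, criterion, n_grid=[5, 15, 30], reps_per_point=2_000, seed=4)
    assert sweep.p_max == max(e.p_hat for e in sweep.estimates)
    assert find_optimum(sweep) == (sweep.n_star, sweep.p_max)


class TestAggregateProduct:
    def test_published_five_study_product(self):
        """The five per-study success rates multiply to 0.003 at 3 d.p."""
        result = aggregate_product(
            {"s1": 0.163, "s2": 0.380, "s3": 0.575, "s4": 0.450, "s5": 0.212}
        )
        assert round(result.p_tes, 3) == 0.003
        assert result.excess_flag  # far below any sensible threshold

    def test_identity_on_single_study(self):
        result = aggregate_product({"only": 0.42})
        assert result.p_tes == 0.42
        assert not result.excess_flag

    def test_permutation_invariance_and_multiplicativity(self):
        probs = {"a": 0.9, "b": 0.5, "c": 0.25, "d": 0.8}
        forward = aggregate_product(probs).p_tes
        reverse = aggregate_product(dict(reversed(list(probs.items())))).p_tes
        assert forward == pytest.approx(reverse, rel=1e-15)
        split = aggregate_product(
            {
                "ab": aggregate_product({k: probs[k] for k in ("a", "b")}).p_tes,
                "cd": aggregate_product({k: probs[k] for k in ("c", "d")}).p_tes,
            }
        ).p_tes
        assert split == pytest.approx(forward, rel=1e-12)
        assert forward <= min(probs.values())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="OUT_OF_RANGE"):
            aggregate_product({"s": 1.2})
        with pytest.raises(ValueError):
            aggregate_product({})
        with pytest.raises(ValueError):
            aggregate_product({"s": 0.5}, threshold=0.0)

    def test_threshold_controls_flag(self):
        assert aggregate_product({"s": 0.05}, threshold=0.1).excess_flag
        assert not aggregate_product({"s": 0.5}, threshold=0.1).excess_flag


def test_ceiling_never_beats_analytic_upper_bound():
    """p_max cannot exceed the product of each test's own analytic ceiling."""
    m0 = MeasureModel(("m1",), [0.0], [1.0], [[1.0]])
    m_sig = MeasureModel(("m1",), [0.5], [1.0], [[1.0]])
    m_non = MeasureModel(("m1",), [0.2], [1.0], [[1.0]])
    design = StudyDesign(
        "mixed",
        (
            ConditionSpec("a", 10, m_sig),
            ConditionSpec("b", 10, m0),
            ConditionSpec("c", 10, m_non),
            ConditionSpec("d", 10, m0),
        ),
    )
    crit = SuccessCriterion(
        (
            TestSpec.between("sig", "a", "b", "m1", Requirement.SIGNIFICANT_IN_DIRECTION, Sign.POSITIVE),
            TestSpec.between("non", "c", "d", "m1", Requirement.NON_SIGNIFICANT),
        )
    )
    grid = list(range(10, 101, 10))
    sweep = success_curve(design, crit, n_grid=grid, reps_per_point=3_000, seed=8)
    ceilings = []
    for n in grid:
        probs = power_two_sample(0.5, n, n)
        ceilings.append(probs.p_sig_in_direction)
    bound = max(ceilings) * max(
        power_two_sample(0.2, n, n).p_nonsig for n in grid
    )
    assert sweep.p_max <= bound + 3 * max(e.mc_se for e in sweep.estimates)
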