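import numpy as np
import pytest

from excess_success import (
    ConditionSpec,
    MeasureModel,
    Requirement,
    Sign,
    StudyDesign,
    SuccessCriterion,
    TestSpec,
    study1_template,
)


@pytest.fixture
def null_two_condition():
    """Two conditions with identical populations: every effect is truly zero."""
    model = MeasureModel(("m1",), [0.0], [1.0], [[1.0]])
    design = StudyDesign(
        "null", (ConditionSpec("a", 20, model), ConditionSpec("b", 20, model))
    )
    return design


@pytest.fixture
def directed_null_criterion():
    return SuccessCriterion(
        (
            TestSpec.between(
                "t1", "a", "b", "m1", Requirement.SIGNIFICANT_IN_DIRECTION, Sign.POSITIVE
            ),
        )
    )


def priming_models(rel_shift_black=-6.0, rel_shift_white=6.0, irrel_shift=0.5, sd=6.0, rho=0.5):
    """Synthetic population parameters for the 3-condition priming template.

    Invented numbers in 'frames to detection' units, shaped like the
    scenario the template encodes: black priming speeds crime-relevant
    detection, white priming slows it, and the crime-irrelevant measure
    carries only a small (but nonzero) priming effect.
    """
    corr = [[1.0, rho], [rho, 1.0]]
    base = 27.0

    def model(rel_mean, irrel_mean):
        return MeasureModel(
            ("crime_relevant", "crime_irrelevant"),
            [rel_mean, irrel_mean],
            [sd, sd],
            corr,
        )

    return {
        "no-prime": model(base, base),
        "black-prime": model(base + rel_shift_black, base - irrel_shift),
        "white-prime": model(base + rel_shift_white, base + irrel_shift),
    }


@pytest.fixture
def priming_study():
    """study1_template instantiated with the synthetic priming parameters."""
    return study1_template(priming_models())
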