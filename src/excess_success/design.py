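"""Declarative representation of an experiment's population model.

A study is described by the population parameters a direct replication
would sample from: per-condition sample sizes, means and standard
deviations for each within-subject measure, and the correlation matrix
among measures.  "Success" for the study is a conjunction of required
hypothesis-test outcomes (significant in a stated direction, or
non-significant), mirroring how multi-test articles tie theoretical
claims to a pattern of test results.

Types here are plain frozen dataclasses; they accept whatever they are
given so that :func:`validate_design` can report *every* violation at
once instead of failing at construction time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MeasureModel",
    "ConditionSpec",
    "StudyDesign",
    "TestKind",
    "Requirement",
    "Sign",
    "TestSpec",
    "SuccessCriterion",
    "Violation",
    "validate_design",
    "with_sample_size",
]

#: eigenvalue tolerance when checking positive semidefiniteness of a
#: correlation matrix; absorbs round-trip float noise from config files.
PSD_EIGENVALUE_TOL = -1e-10


class TestKind(str, enum.Enum):
    """Which t-test a :class:`TestSpec` requests."""

    __test__ = False  # not a pytest class, despite the name

    BETWEEN_TWO_SAMPLE = "between"
    WITHIN_PAIRED = "within"


class Requirement(str, enum.Enum):
    """The outcome a test must produce for the study to count as successful."""

    SIGNIFICANT_IN_DIRECTION = "significant"
    NON_SIGNIFICANT = "non_significant"


class Sign(str, enum.Enum):
    """Expected direction of a mean difference (A − B, or m1 − m2)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


def _as_float_array(x, ndim: int) -> np.ndarray:
    arr = np.array(x, dtype=float)
    if arr.ndim != ndim:
        arr = np.atleast_1d(arr) if ndim == 1 else np.atleast_2d(arr)
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True, eq=False)
class MeasureModel:
    """Population model of the within-subject measures in one condition.

    Parameters
    ----------
    measure_labels
        Names of the measures, e.g. ``("crime_relevant", "crime_irrelevant")``.
    means, sds
        Population mean and standard deviation per measure, in response
        units (e.g. frames to detection).
    correlations
        Correlation matrix among the measures (unit diagonal, symmetric,
        positive semidefinite).
    """

    measure_labels: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    correlations: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "measure_labels", tuple(self.measure_labels))
        object.__setattr__(self, "means", _as_float_array(self.means, 1))
        object.__setattr__(self, "sds", _as_float_array(self.sds, 1))
        object.__setattr__(self, "correlations", _as_float_array(self.correlations, 2))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasureModel):
            return NotImplemented
        return (
            self.measure_labels == other.measure_labels
            and np.array_equal(self.means, other.means)
            and np.array_equal(self.sds, other.sds)
            and np.array_equal(self.correlations, other.correlations)
        )

    __hash__ = None

    @property
    def n_measures(self) -> int:
        return len(self.measure_labels)

    def covariance(self) -> np.ndarray:
        """Σ_ij = sd_i · sd_j · r_ij."""
        return np.outer(self.sds, self.sds) * self.correlations


@dataclass(frozen=True)
class ConditionSpec:
    """One between-subject condition: a label, a sample size, a population."""

    label: str
    n: int
    model: MeasureModel


@dataclass(frozen=True)
class StudyDesign:
    """A complete experiment: named conditions sharing one measure set."""

    study_label: str
    conditions: tuple[ConditionSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def measure_labels(self) -> tuple[str, ...]:
        return self.conditions[0].model.measure_labels if self.conditions else ()

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    def condition(self, label: str) -> ConditionSpec:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class TestSpec:
    """One hypothesis test and the outcome it must produce.

    ``conditions``/``measures`` encode the operands:

    * between-subjects: ``conditions=(A, B)``, ``measures=(m,)`` —
      compare measure *m* across conditions A and B (difference A − B);
    * within-subjects: ``conditions=(c,)``, ``measures=(m1, m2)`` —
      paired comparison of the two measures inside condition *c*
      (difference m1 − m2).

    A wrong-direction significant result never satisfies a
    ``SIGNIFICANT_IN_DIRECTION`` requirement: replicating a reported
    pattern means reproducing the sign, not merely rejecting the null.
    """

    __test__ = False

    test_id: str
    kind: TestKind
    conditions: tuple[str, ...]
    measures: tuple[str, ...]
    required: Requirement
    expected_sign: Sign = Sign.NONE
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TestKind(self.kind))
        object.__setattr__(self, "required", Requirement(self.required))
        object.__setattr__(self, "expected_sign", Sign(self.expected_sign))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "measures", tuple(self.measures))

    @classmethod
    def between(
        cls,
        test_id: str,
        condition_a: str,
        condition_b: str,
        measure: str,
        required: Requirement,
        expected_sign: Sign = Sign.NONE,
        alpha: float = 0.05,
    ) -> "TestSpec":
        return cls(
            test_id,
            TestKind.BETWEEN_TWO_SAMPLE,
            (condition_a, condition_b),
            (measure,),
            required,
            expected_sign,
            alpha,
        )

    @classmethod
    def within(
        cls,
        test_id: str,
        condition: str,
        measure_a: str,
        measure_b: str,
        required: Requirement,
        expected_sign: Sign = Sign.NONE,
        alpha: float = 0.05,
    ) -> "TestSpec":
        return cls(
            test_id,
            TestKind.WITHIN_PAIRED,
            (condition,),
            (measure_a, measure_b),
            required,
            expected_sign,
            alpha,
        )


@dataclass(frozen=True)
class SuccessCriterion:
    """Conjunction of test requirements defining full replication success."""

    tests: tuple[TestSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tests", tuple(self.tests))

    def __len__(self) -> int:
        return len(self.tests)


@dataclass(frozen=True)
class Violation:
    """One broken invariant, with a machine-readable code."""

    code: str
    message: str


def _check_measure_model(model: MeasureModel, where: str) -> list[Violation]:
    out: list[Violation] = []
    k = len(model.measure_labels)
    if not (len(model.means) == len(model.sds) == k == model.correlations.shape[0]):
        out.append(
            Violation(
                "LENGTH_MISMATCH",
                f"{where}: means/sds/labels/correlation dimensions disagree "
                f"({len(model.means)}/{len(model.sds)}/{k}/{model.correlations.shape})",
            )
        )
        return out  # downstream checks assume consistent shapes
    if model.correlations.shape != (k, k):
        out.append(Violation("LENGTH_MISMATCH", f"{where}: correlation matrix not {k}x{k}"))
        return out
    if np.any(model.sds <= 0) or not np.all(np.isfinite(model.sds)):
        out.append(Violation("SD_NOT_POSITIVE", f"{where}: all sds must be finite and > 0"))
    r = model.correlations
    if np.any(np.abs(r) > 1) or not np.all(np.isfinite(r)):
        out.append(Violation("CORR_OUT_OF_RANGE", f"{where}: correlations must lie in [-1, 1]"))
    if not np.allclose(np.diag(r), 1.0, atol=1e-12):
        out.append(Violation("CORR_DIAGONAL", f"{where}: correlation diagonal must be 1"))
    if not np.allclose(r, r.T, atol=1e-12):
        out.append(Violation("CORR_NOT_SYMMETRIC", f"{where}: correlation matrix must be symmetric"))
    elif np.all(np.isfinite(r)):
        eigmin = float(np.linalg.eigvalsh(r).min())
        if eigmin < PSD_EIGENVALUE_TOL:
            out.append(
                Violation(
                    "CORR_NOT_PSD",
                    f"{where}: correlation matrix not positive semidefinite "
                    f"(min eigenvalue {eigmin:.3g})",
                )
            )
    return out


def _check_test(test: TestSpec, design: StudyDesign, where: str) -> list[Violation]:
    out: list[Violation] = []
    cond_labels = set(design.condition_labels)
    measures = set(design.measure_labels)
    if test.kind is TestKind.BETWEEN_TWO_SAMPLE:
        ok_shape = len(test.conditions) == 2 and len(test.measures) == 1
    else:
        ok_shape = len(test.conditions) == 1 and len(test.measures) == 2
    if not ok_shape:
        out.append(
            Violation("BAD_OPERANDS", f"{where}: wrong operand arity for {test.kind.value} test")
        )
    unresolved = [c for c in test.conditions if c not in cond_labels]
    unresolved += [m for m in test.measures if m not in measures]
    if unresolved:
        out.append(
            Violation("UNRESOLVED_OPERAND", f"{where}: unknown operand(s) {unresolved}")
        )
    if not (0.0 < test.alpha < 1.0):
        out.append(Violation("BAD_ALPHA", f"{where}: alpha must be in (0, 1)"))
    if test.required is Requirement.SIGNIFICANT_IN_DIRECTION:
        if test.expected_sign is Sign.NONE:
            out.append(
                Violation(
                    "MISSING_EXPECTED_SIGN",
                    f"{where}: significant-in-direction tests need an expected sign",
                )
            )
    elif test.expected_sign is not Sign.NONE:
        out.append(
            Violation(
                "UNEXPECTED_SIGN",
                f"{where}: non-significance requirements carry no expected sign",
            )
        )
    return out


def validate_design(
    design: StudyDesign, criterion: SuccessCriterion | None = None
) -> list[Violation]:
    """Check every structural invariant; return all violations (empty = valid).

    Pure and idempotent: no exception is raised for an invalid input and
    repeated calls return identical lists.
    """
    out: list[Violation] = []
    if not design.conditions:
        out.append(Violation("EMPTY_DESIGN", "design has no conditions"))
        return out
    labels = [c.label for c in design.conditions]
    if len(set(labels)) != len(labels):
        out.append(Violation("DUPLICATE_CONDITION", f"condition labels not unique: {labels}"))
    ref = design.conditions[0].model.measure_labels
    for cond in design.conditions:
        where = f"condition '{cond.label}'"
        if int(cond.n) != cond.n or cond.n < 2:
            out.append(Violation("N_TOO_SMALL", f"{where}: n must be an integer ≥ 2"))
        if cond.model.measure_labels != ref:
            out.append(
                Violation(
                    "MEASURES_MISMATCH",
                    f"{where}: measure labels differ from first condition",
                )
            )
        out.extend(_check_measure_model(cond.model, where))
    if criterion is not None:
        if len(criterion.tests) == 0:
            out.append(Violation("EMPTY_CRITERION", "criterion has no tests"))
        ids = [t.test_id for t in criterion.tests]
        if len(set(ids)) != len(ids):
            out.append(Violation("DUPLICATE_TEST_ID", f"test ids not unique: {ids}"))
        for t in criterion.tests:
            out.extend(_check_test(t, design, f"test '{t.test_id}'"))
    return out


def with_sample_size(design: StudyDesign, n: int) -> StudyDesign:
    """Return a copy of *design* with every condition's n replaced by *n*.

    Used by sample-size sweeps (equal allocation across conditions).
    """
    return replace(
        design, conditions=tuple(replace(c, n=int(n)) for c in design.conditions)
    )
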