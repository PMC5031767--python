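"""Exception hierarchy for the excess-success toolkit."""


class ExcessSuccessError(Exception):
    """Base class for all package errors."""


class DegenerateSampleError(ExcessSuccessError):
    """A sample (or pair of samples) has zero variance, so no t statistic exists.

    Under a continuous population model this has probability zero; its
    occurrence signals a malformed design (e.g. a zero SD), not an unlucky
    draw, so Monte-Carlo estimation aborts rather than counting it as failure.
    """


class InsufficientRepsError(ExcessSuccessError):
    """Too few Monte-Carlo replications for a meaningful estimate (< 100)."""


class KindMismatchError(ExcessSuccessError):
    """An effect size of the wrong kind (between-d vs paired-dz) was supplied."""


class InvalidDesignError(ExcessSuccessError):
    """A study design / success criterion failed validation.

    Carries the full list of :class:`~excess_success.design.Violation`
    records so callers can report every problem at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.code}: {v.message}" for v in self.violations)
        super().__init__(f"invalid design: {lines}")


class ParseError(ExcessSuccessError):
    """A spec or parameter file failed to parse; message names the location."""


class SchemaVersionError(ParseError):
    """The spec file declares an unsupported spec_version."""
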