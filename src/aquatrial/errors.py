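"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed inputs (bad table cells, broken
invariants); ``DomainError`` covers mathematically inadmissible values
(nonpositive weights, zero denominators); the remaining classes are
narrower, self-describing variants.  The CLI maps ``ValidationError`` and
its subclasses to exit code 1 and everything else to exit code 2.
"""


class AquatrialError(Exception):
    """Base class for all package errors."""


class ValidationError(AquatrialError, ValueError):
    """An input violates a structural invariant (bad cell, bad key, bad shape)."""


class DomainError(AquatrialError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class MissingIngredientError(ValidationError, KeyError):
    """A formulation references an ingredient with no profile."""


class InfeasibleFormulationError(ValidationError):
    """Non-filler inclusions already exceed 100% of dry matter."""


class DegenerateInputError(DomainError):
    """Too few or too degenerate data points for a regression."""


class FixtureIntegrityError(AquatrialError):
    """A packaged data file does not match its recorded checksum."""


class NegativeAdcWarning(UserWarning):
    """A computed apparent digestibility coefficient is negative.

    Negative ADCs are mathematically possible under marker measurement
    noise and are reported as-is, not clamped.
    """
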