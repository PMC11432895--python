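"""Exception hierarchy for the bimast package."""


class BimastError(Exception):
    """Base class for all package errors."""


class ValidationError(BimastError, ValueError):
    """An input object violates a documented invariant.

    The message always names the offending field.
    """


class CohortSpecError(ValidationError):
    """A CohortSpec field is invalid."""


class CohortCSVError(ValidationError):
    """A cohort CSV file is malformed; the message carries the row number."""


class DomainError(ValidationError):
    """A score was evaluated outside its mathematical domain."""


class StrategyError(ValidationError):
    """A screening-strategy definition is malformed or unknown."""


class DerivationError(ValidationError):
    """A statistical routine received degenerate input (single class, empty)."""


class EconConfigError(ValidationError):
    """A health-economic configuration field is invalid."""


class ConvergenceWarning(UserWarning):
    """A fit terminated without meeting its convergence criterion."""
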