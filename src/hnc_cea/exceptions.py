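"""Exception hierarchy.

All package errors derive from :class:`CEAError` so callers can catch one
type; the subclasses distinguish bad user input, bad configuration, model
structure violations, and numerical/model failures.
"""


class CEAError(Exception):
    """Base class for all errors raised by hnc_cea."""


class InvalidInputError(CEAError, ValueError):
    """A value violates a documented precondition (negative cost, bad level...)."""


class ConfigurationError(CEAError):
    """A config/value-set/parameter file is internally inconsistent or incomplete."""


class MatrixValidationError(CEAError):
    """A transition matrix violates row-stochasticity or a structural rule."""


class ModelError(CEAError):
    """The model cannot be evaluated (e.g. no absorbing state reachable)."""
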