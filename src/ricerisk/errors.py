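"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`RiceRiskError` so callers (and the
CLI) can distinguish configuration problems, malformed data and numerical
failures from programming errors.
"""


class RiceRiskError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RiceRiskError, ValueError):
    """An argument violates a documented precondition (negative dose, empty list...)."""


class InvalidToxicologyError(RiceRiskError, ValueError):
    """A toxicological constant is missing, non-positive or inconsistent."""


class NotCarcinogenicError(RiceRiskError, ValueError):
    """Carcinogenic risk requested for an element without a slope factor."""


class MalformedRecordError(RiceRiskError, ValueError):
    """A sample record is internally inconsistent (e.g. uncensored but value-less)."""


class DegenerateDataError(RiceRiskError, ValueError):
    """The data admit no meaningful fit or statistic (all values identical, empty cell...)."""


class FitFailureError(RiceRiskError, RuntimeError):
    """A maximum-likelihood fit failed to converge; carries diagnostics in args."""


class InvalidConfigError(RiceRiskError, ValueError):
    """A configuration file or object violates the schema."""
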