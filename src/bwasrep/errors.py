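"""Exception hierarchy shared across the package."""


class BwasrepError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BwasrepError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class DataError(BwasrepError, ValueError):
    """A dataset violates its invariants (missing values, inconsistent shapes)."""


class SizeError(BwasrepError, ValueError):
    """A sample-size precondition is violated (too few samples, infeasible split)."""


class FitError(BwasrepError, RuntimeError):
    """Model fitting cannot proceed (constant outcome, degenerate inputs)."""


class ConstantInputError(BwasrepError, ValueError):
    """A correlation was requested on a constant vector; r is undefined."""


class NumericalError(BwasrepError, RuntimeError):
    """A linear-algebra step failed; the message suggests a remedy."""
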