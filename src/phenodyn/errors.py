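"""Exception hierarchy shared across the package."""


class PhenodynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhenodynError, ValueError):
    """A generator or simulator configuration violates its invariants."""


class GenerationError(PhenodynError, ValueError):
    """A synthetic-data request cannot be satisfied (e.g. negative variance)."""


class ProtocolViolationError(PhenodynError, RuntimeError):
    """A propagation protocol guard was hit (e.g. transfer below the minimum)."""


class DegenerateDistributionError(PhenodynError, ValueError):
    """An operation that needs spread was given a zero-variance sample."""


class FitError(PhenodynError, ValueError):
    """A regression design is degenerate or a fit cannot be computed."""


class ParseError(PhenodynError, ValueError):
    """A delimited input table is malformed; message names the offending line."""


class FormatError(PhenodynError, ValueError):
    """An image stack or file set does not satisfy the expected format."""


class UndefinedDenominatorError(PhenodynError, ZeroDivisionError):
    """A ratio estimator's denominator is zero (e.g. no colonies on rich plates)."""
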