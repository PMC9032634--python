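"""Exception hierarchy for hegbayes."""


class HegBayesError(Exception):
    """Base class for all hegbayes errors."""


class ValidationError(HegBayesError, ValueError):
    """An input value violates a domain invariant (e.g. non-positive concentration)."""


class FormatError(HegBayesError, ValueError):
    """A file does not conform to the expected schema."""


class InsufficientDataError(HegBayesError, ValueError):
    """Too few measurements to compute the requested quantity."""


class ConfigurationError(HegBayesError, ValueError):
    """Inconsistent sampler or prior configuration (e.g. an empty truncation region)."""


class DegenerateTruncationError(HegBayesError, ArithmeticError):
    """The probability mass inside a truncation interval is numerically zero."""
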