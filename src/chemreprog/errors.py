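"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError / ParseError -> 3,
everything else raised during a stage -> 4.
"""


class ChemreprogError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemreprogError):
    """Input violates a documented precondition or invariant."""


class ParseError(ChemreprogError):
    """A file could not be parsed; message names the offending line."""


class RangeError(ValidationError):
    """A coordinate or interval falls outside its valid range."""


class NormalizationError(ChemreprogError):
    """Size-factor normalization is undefined for the given matrix."""


class UndefinedResultError(ChemreprogError):
    """A summary statistic is undefined (e.g. a proportion over zero events)."""


class ComputationError(ChemreprogError):
    """A stage failed while computing (not an input problem)."""
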