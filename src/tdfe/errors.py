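"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2, I/O errors -> 3,
numeric / degenerate-input errors -> 4.
"""


class TDFEError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TDFEError):
    """A file does not conform to the expected dialect (missing columns, short lines)."""


class ParseError(TDFEError):
    """A value in an input file could not be parsed; message names the offending line."""


class EmptyTensorError(TDFEError):
    """No compounds survive the completeness filter, or an input collection is empty."""


class DegenerateInputError(TDFEError):
    """Numerically degenerate input: zero-variance component, constant covariate, etc."""
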