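"""Typed errors raised across the package.

The CLI maps these onto exit codes: configuration problems exit 2,
data/format problems exit 3.
"""


class MutembedError(Exception):
    """Base class for all package errors."""


class FormatError(MutembedError):
    """A file does not conform to its declared format."""


class EmptyInputError(FormatError):
    """An input file contains no usable records."""


class ValidationError(MutembedError):
    """Well-formed input violates a semantic constraint."""


class DegenerateInputError(ValidationError):
    """Numerically degenerate input (e.g. zero-variance matrix for PCA)."""


class ConfigurationError(MutembedError):
    """Invalid parameter values or an inconsistent pipeline configuration."""
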