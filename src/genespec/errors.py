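"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (click's default),
:class:`ValidationError`/:class:`FormatError` exit 3, and
:class:`DegenerateDataError`/:class:`BalanceError` exit 4.
"""


class GenespecError(Exception):
    """Base class for all package errors."""


class FormatError(GenespecError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(GenespecError):
    """Input data violates an invariant (negative values, missing ids, ...)."""


class DegenerateDataError(GenespecError):
    """Data too degenerate to compute on (empty result, collapsed partition)."""


class BalanceError(GenespecError):
    """A category x condition pair has no sample, so balanced draws are impossible."""
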