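"""Exception hierarchy shared across the package.

All validation problems raise :class:`ValidationError`; misconfigured
simulations raise :class:`ConfigurationError`; statistics that are
mathematically undefined for the given input (for example colourQ with no
Colour-A peaks) raise :class:`UndefinedStatisticError` rather than
returning a silent sentinel value.
"""


class CCSError(Exception):
    """Base class for all package errors."""


class ValidationError(CCSError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(CCSError, ValueError):
    """A configuration object is internally inconsistent."""


class UndefinedStatisticError(CCSError):
    """A requested statistic is undefined for the given input."""


class UnmappedReadError(CCSError):
    """A peptide read does not occur in the parent protein sequence."""


class AmbiguousReadError(CCSError):
    """A peptide read occurs at more than one position in the parent."""


class EmptyProfileError(CCSError):
    """No reads could be mapped, so no protection profile exists."""
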