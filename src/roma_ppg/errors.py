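"""Exception hierarchy for the roma_ppg package.

All package-specific failures derive from :class:`RomaError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class RomaError(Exception):
    """Base class for all roma_ppg errors."""


class FormatError(RomaError):
    """A file could not be parsed as the expected format."""


class DataError(RomaError):
    """Input data violate a precondition (empty, non-monotone, single-class, ...)."""


class ConfigurationError(RomaError):
    """A configuration value is unresolvable or physically impossible (e.g. cutoff >= Nyquist)."""
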