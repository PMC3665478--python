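"""Exception hierarchy.

Everything raised on bad user input derives from :class:`SapgoError` so callers
(and the CLI) can distinguish data problems from bugs.
"""


class SapgoError(Exception):
    """Base class for all package errors."""


class FormatError(SapgoError):
    """Malformed input file or token."""


class IntegrityError(SapgoError):
    """Input parses but violates an internal consistency contract."""


class ConfigError(SapgoError):
    """Invalid configuration (missing column, even window, bad preset...)."""


class LookupFailure(SapgoError):
    """A requested entity (chain, residue, GO term) is absent."""


class MappingError(SapgoError):
    """A variant cannot be mapped onto a structure residue."""


class CompatibilityError(SapgoError):
    """Model/feature layout mismatch or unreadable model file."""


class TrainingError(SapgoError):
    """Unusable training input (single class, empty set...)."""


class UndefinedMetricError(SapgoError):
    """A performance index is undefined on the given counts (zero denominator)."""
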