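"""Exception hierarchy.

All library-raised errors derive from :class:`FFDRegError` so callers can
catch everything from one base while still distinguishing bad data
(:class:`DomainError`), inconsistent setup (:class:`ConfigurationError`)
and file problems (:class:`FormatError`).
"""


class FFDRegError(Exception):
    """Base class for all ffdreg errors."""


class DomainError(FFDRegError, ValueError):
    """Input values outside the mathematical domain of an operation."""


class ConfigurationError(FFDRegError, ValueError):
    """Mutually inconsistent shapes, spacings or settings."""


class FormatError(FFDRegError, IOError):
    """Unreadable, unwritable or unsupported file content."""
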