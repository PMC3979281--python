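"""Exception hierarchy.

All domain errors derive from :class:`SwerfError` so callers can catch the
package's failures with a single except clause; each also derives from the
closest builtin (ValueError / RuntimeError) so idiomatic generic handling
keeps working.
"""


class SwerfError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(SwerfError, ValueError):
    """An argument is outside the physically meaningful domain."""


class FormatError(SwerfError, ValueError):
    """An input file violates the documented CSV dialect."""


class ConfigurationError(SwerfError, ValueError):
    """Required material metadata or configuration is missing."""


class InvalidStateError(SwerfError, RuntimeError):
    """An operation was called on an object in the wrong state
    (e.g. converting an already-aerodynamic distribution)."""


class NumericalError(SwerfError, RuntimeError):
    """A numerical routine failed to reach its accuracy target."""
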