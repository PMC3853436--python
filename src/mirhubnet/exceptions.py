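"""Exception hierarchy.

All errors raised on bad user input derive from :class:`MirhubnetError` so
callers can catch the package's failures with one clause; they also derive
from ``ValueError`` to stay idiomatic.
"""


class MirhubnetError(Exception):
    """Base class for all mirhubnet errors."""


class FormatError(MirhubnetError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ParameterError(MirhubnetError, ValueError):
    """An argument is outside its documented domain."""


class InputError(MirhubnetError, ValueError):
    """In-memory inputs violate an operation's precondition."""
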