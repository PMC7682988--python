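"""Exception hierarchy.

``ValidationError`` marks malformed data, ``ConfigurationError`` marks an
inconsistent request (missing sample classes, unknown labels), and
``ComputationError`` marks a numerically impossible step (zero bait after
flooring, zero denominator). The CLI maps all three to exit code 1 and
usage mistakes to exit code 2.
"""


class TxportError(Exception):
    """Base class for all package errors."""


class ValidationError(TxportError):
    """Input data violates a documented invariant."""


class ConfigurationError(TxportError):
    """The requested analysis is inconsistent with the supplied inputs."""


class ComputationError(TxportError):
    """A required quantity cannot be computed from the data."""
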