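"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ``InputError`` (and subclasses) → 2,
``ConfigError`` → 3.
"""


class RiceQError(Exception):
    """Base class for all package errors."""


class InputError(RiceQError):
    """Unreadable, malformed or otherwise invalid input data."""

    exit_code = 2


class ConfigError(RiceQError):
    """Invalid parameter or configuration value."""

    exit_code = 3


class SegmentationError(InputError):
    """A force curve could not be split into two compression cycles."""
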