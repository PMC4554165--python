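"""Exception hierarchy.

Every user-facing error derives from :class:`MirscarError` so callers
(and the CLI) can catch pipeline failures distinctly from bugs.
"""


class MirscarError(Exception):
    """Base class for all mirscar errors."""


class ConfigurationError(MirscarError, ValueError):
    """An invalid configuration value; the message names the field."""


class InputError(MirscarError, ValueError):
    """Malformed or inconsistent input data."""


class DesignError(InputError):
    """The sample sheet does not define a complete paired design."""


class ParseError(InputError):
    """A file could not be parsed; the message carries the line number."""
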