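"""Exception hierarchy.

All package errors derive from :class:`GliosigError` so callers can catch
broadly; the subclasses distinguish bad configuration, malformed files and
invalid data values.
"""


class GliosigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GliosigError, ValueError):
    """A parameter or configuration field is invalid; the message names it."""


class FormatError(GliosigError, ValueError):
    """An input file is missing, malformed or dimension-inconsistent."""


class ValidationError(GliosigError, ValueError):
    """Data failed a validation contract (e.g. signature detection)."""
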