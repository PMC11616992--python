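"""Exception hierarchy.

All package errors derive from :class:`LspnetError` so callers (and the CLI)
can distinguish input, configuration and computation failures.
"""


class LspnetError(Exception):
    """Base class for all lspnet errors."""


class InputError(LspnetError):
    """Unreadable, malformed or out-of-range input data."""


class SelectionError(InputError):
    """An atom/node selection resolved to nothing usable."""


class FormatError(InputError):
    """Structurally inconsistent input (e.g. varying atom counts per model)."""


class DataError(InputError):
    """A required atom or node is missing from a frame."""


class RangeError(InputError):
    """A requested time window lies outside the trajectory span."""


class ComparisonError(LspnetError):
    """Two objects that must share a node set do not."""


class ConfigError(LspnetError):
    """Invalid parameter or option value."""


class DegenerateInputError(LspnetError):
    """Input is valid but too small/degenerate for the requested operation."""
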