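"""Exception hierarchy for microloop.

All user-facing failures derive from :class:`MicroloopError` so callers
(and the CLI) can catch one base class.
"""


class MicroloopError(Exception):
    """Base class for all microloop errors."""


class InputError(MicroloopError, ValueError):
    """Malformed or physically impossible input data."""


class ParameterError(MicroloopError, ValueError):
    """A configuration or model parameter outside its documented range."""


class ConfigurationError(MicroloopError):
    """An experiment bundle or pipeline configuration that cannot be analysed."""


class DegenerateDataError(MicroloopError):
    """Data with zero variance (or similar) where a test statistic is undefined."""
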