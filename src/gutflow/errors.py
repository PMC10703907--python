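"""Exception hierarchy.

All gutflow errors derive from :class:`GutflowError` so callers can catch one
type; the subclasses mirror the three failure modes of the pipeline: malformed
input files, invalid analysis parameters, and inconsistent configuration.
"""


class GutflowError(ValueError):
    """Base class for all errors raised by gutflow."""


class FormatError(GutflowError):
    """A trace/drops file or an in-memory recording violates the data model."""


class ParameterError(GutflowError):
    """An analysis parameter is out of its valid range for the given input."""


class ConfigError(GutflowError):
    """An analysis or simulation configuration is internally inconsistent."""
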