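"""Typed exceptions shared across the pipeline.

Every reader and every numerical operation raises one of these rather than a
bare ValueError, so callers (and the CLI exit-code mapping) can distinguish
bad configuration, malformed data, and undefined mathematics.
"""


class FlorealmError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FlorealmError):
    """A parameter violates an operation's preconditions."""


class FormatError(FlorealmError):
    """An external file does not conform to its declared format."""


class ConsistencyError(FlorealmError):
    """Two in-memory objects that must agree do not (id sets, time grids...)."""


class UndefinedBetaError(FlorealmError):
    """Simpson beta requested for a pair where a + min(b, c) = 0."""


class GenerationError(FlorealmError):
    """The synthetic generator could not satisfy its postconditions."""


class InsufficientDataError(FlorealmError):
    """Too few observations for the requested statistic."""
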