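"""Exception hierarchy for the reconfiguration pipeline.

Every stage raises a subclass of :class:`ReconfigError` so the CLI can
abort with the stage name and the offending subject attached.
"""


class ReconfigError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(ReconfigError):
    """A file or table does not have the expected columns/shape."""


class ParseError(ReconfigError):
    """A cell or field could not be parsed; carries row context."""


class StructureError(ReconfigError):
    """Task/event structure violates the block design invariants."""


class StateError(ReconfigError):
    """An operation was called before its inputs were prepared."""


class ParameterError(ReconfigError):
    """A configuration value is outside its valid domain."""


class DataError(ReconfigError):
    """Degenerate data (zero variance, too few samples) for a statistic."""


class ScopeError(ReconfigError):
    """An edge set is too small to support a similarity value."""


class JoinError(ReconfigError):
    """Tables could not be aligned by subject."""
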