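"""Exception hierarchy shared across the toolkit."""


class DaqRefineError(Exception):
    """Base class for all toolkit errors."""


class ParseError(DaqRefineError):
    """A file could not be parsed into the requested domain object."""


class ValidationError(DaqRefineError):
    """A domain-object invariant was violated."""


class GeometryMismatchError(DaqRefineError):
    """Model and volume do not share a coordinate frame (most lookups fall off-grid)."""


class DegenerateGeometryError(DaqRefineError):
    """Point sets too degenerate (collinear/coincident) for a rigid superposition."""
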