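"""Package exception hierarchy."""


class RigiposeError(Exception):
    """Base class for all package errors."""


class ParseError(RigiposeError):
    """A keypoint or AU file could not be parsed."""


class SchemaError(RigiposeError):
    """Input violated an expected layout (joint count, columns, stat sets)."""


class RejectionError(RigiposeError):
    """A recording failed quality control (too much missing data)."""


class DegenerateGeometryError(RigiposeError):
    """Geometry needed for normalization collapsed (zero trunk length)."""


class DegenerateTrainingError(RigiposeError):
    """Training data cannot support a multiclass model (single class)."""


class LabelError(RigiposeError):
    """An ordinal label fell outside the supported 0-3 range."""
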