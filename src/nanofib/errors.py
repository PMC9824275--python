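"""Exception hierarchy shared across the package."""


class NanofibError(Exception):
    """Base class for all package errors."""


class UnsupportedMaterialError(NanofibError, ValueError):
    """Requested polymer material has no registered coarse-grained mapping."""


class InvalidArgumentError(NanofibError, ValueError):
    """An argument violates an operation precondition."""


class PackingError(NanofibError, RuntimeError):
    """Random placement could not satisfy the clash/spacing constraint."""


class PlacementError(PackingError):
    """Nanoparticle placement constraint unsatisfiable in the given box."""


class NumericalFailureError(NanofibError, FloatingPointError):
    """Non-finite forces or coordinates encountered during integration."""


class UndefinedStatisticError(NanofibError, ValueError):
    """A statistic is undefined for this input (e.g. no charged beads)."""


class ModelShapeError(NanofibError, ValueError):
    """A structure does not have the expected chain/residue layout."""


class AnnotationError(NanofibError, KeyError):
    """Residue code unknown to the annotation scheme."""


class DegenerateGeometryError(NanofibError, ValueError):
    """Geometry is degenerate for the requested computation."""


class ParseError(NanofibError, ValueError):
    """A structure file could not be parsed."""


class FormatError(NanofibError, ValueError):
    """Unknown or unsupported file format."""


class EncodingError(NanofibError, ValueError):
    """Document cannot be encoded in the requested format."""


class ConfigurationError(NanofibError, ValueError):
    """Invalid or inconsistent run configuration."""


class InputConsistencyError(NanofibError, ValueError):
    """Inputs to an analysis disagree (e.g. component index vs frame size)."""
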