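"""Exception hierarchy for hydrashell."""


class HydrashellError(Exception):
    """Base class for all hydrashell errors."""


class FormatError(HydrashellError):
    """Malformed or inconsistent input file (e.g. atom-count mismatch)."""


class EmptyInputError(HydrashellError):
    """Trajectory or selection contains no usable data."""


class SamplingError(HydrashellError):
    """Frame timestamps are not uniformly spaced."""


class GeometryError(HydrashellError):
    """Invalid box or unsupported cell geometry."""


class SelectionError(HydrashellError):
    """An atom selection is empty or out of range."""


class DegenerateFitError(HydrashellError):
    """Superposition fit set is too small or collinear."""


class ParameterError(HydrashellError):
    """A numeric parameter is out of its valid range."""


class NormalizationError(HydrashellError):
    """Bulk normalization shell contains no grid nodes."""


class UndefinedCurveError(HydrashellError):
    """Survival curve undefined (site never occupied)."""


class SchemaError(HydrashellError):
    """Report schema versions do not match."""
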