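"""Exception types shared across the toolkit."""


class OamorphError(ValueError):
    """Base class for all domain errors raised by oamorph."""


class UnitError(OamorphError):
    """Physical units are missing or ambiguous (e.g. no voxel size)."""


class GeometryError(OamorphError):
    """Unsupported geometry, e.g. anisotropic voxel spacing."""


class SurfaceQualityError(OamorphError):
    """Too few columns yielded a cartilage surface inside the ROI."""


class UnderdeterminedFitError(OamorphError):
    """Fewer observations than the polynomial fit requires."""


class EmptyROIError(OamorphError):
    """An ROI is empty, or an operation emptied it (e.g. over-erosion)."""


class WindowError(OamorphError):
    """Too few samples inside the requested analysis window."""


class SchemaError(OamorphError):
    """A tabular input does not match the documented column schema."""
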