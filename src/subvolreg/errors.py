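"""Exception types shared across the package."""


class SubvolregError(Exception):
    """Base class for all package errors."""


class GeometryError(SubvolregError):
    """Two gridded objects do not share shape/spacing/origin within tolerance."""


class EmptyMaskError(SubvolregError):
    """An operation that requires a non-empty delineation received an empty mask."""


class FieldOfViewError(SubvolregError):
    """A simulated organ displacement pushes the organ outside the image grid."""


class OverlapError(SubvolregError):
    """Too few mask voxels map inside the fixed image to evaluate the metric."""


class DegenerateSampleError(SubvolregError):
    """A variance test received a sample with zero variance in the denominator."""


class InsufficientPairsError(SubvolregError):
    """A statistic that needs at least two observations per group got fewer."""


class UnpairedError(SubvolregError):
    """A paired analysis is missing one side of a pair."""


class IncompletePairError(SubvolregError):
    """A per-pair comparison across registration volumes is missing entries."""
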