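"""Exception hierarchy shared by the pipeline modules."""


class PaquantError(Exception):
    """Base class for all package errors."""


class GeometryError(PaquantError):
    """A region, contour or ellipsoid is inconsistent with the volume geometry."""


class DegenerateGeometryError(GeometryError):
    """Point set is rank-deficient (coplanar/collinear) for ellipsoid fitting.

    Attributes
    ----------
    rank : int
        Affine rank of the offending point set.
    """

    def __init__(self, message: str, rank: int):
        super().__init__(message)
        self.rank = rank


class ConfigurationError(PaquantError):
    """Invalid configuration: missing wavelengths, bad thresholds, bad quotas."""


class DataError(PaquantError):
    """Invalid data values: non-positive energies, empty samples, shape mismatch."""
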