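"""Exception types shared across the package."""


class EigenFundusError(Exception):
    """Base class for all package-specific errors."""


class DegeneratePatchError(EigenFundusError):
    """Raised when a patch has zero intensity range and cannot be normalized."""


class NoCandidatesError(EigenFundusError):
    """Raised when a distance map holds no evaluated cells to search."""


class GeometryError(EigenFundusError):
    """Raised when grids, masks or images have incompatible shapes."""
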