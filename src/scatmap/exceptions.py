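"""Exception hierarchy for scatmap."""


class ScatmapError(Exception):
    """Base class for all scatmap-specific errors."""


class CalibrationError(ScatmapError):
    """Raised when a geometry or mosaic calibration cannot be performed.

    Carries a ``diagnostics`` dict describing what was (not) detected.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MergeError(ScatmapError):
    """Raised when two 1D profiles cannot be merged (insufficient overlap)."""


class SchemaError(ScatmapError):
    """Raised when an HDF5 scan file is missing a required dataset."""


class NonLinearAttributeError(ScatmapError):
    """Raised when a non-linear attribute is offered for sinogram building.

    Ratios must be formed after reconstruction, never on sinograms.
    """
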