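"""Exception hierarchy shared across the pipeline stages."""


class ColonyGridError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ColonyGridError):
    """A log/key/stats file does not follow the documented dialect."""


class IntegrityError(ColonyGridError):
    """Data violates an invariant (duplicate positions, out-of-bounds, ...)."""


class SplitError(ColonyGridError):
    """A multi-plate scan did not split into the declared plate arrangement."""


class AlignmentError(ColonyGridError):
    """Rotation/pitch estimation failed or an angle is out of range."""


class CropError(ColonyGridError):
    """Fine cropping walked off the image without finding the grid border."""


class MeasurementError(ColonyGridError):
    """Quantification failed (e.g. the quality-control check)."""


class NormalizationError(ColonyGridError):
    """A plate cannot be normalized (zero median, missing controls)."""


class PairingError(ColonyGridError):
    """Control/experimental plates cannot be matched up."""


class ConfigError(ColonyGridError):
    """Invalid run configuration."""
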