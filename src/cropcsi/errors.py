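"""Exception hierarchy shared across the pipeline stages."""


class CropCsiError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CropCsiError):
    """Invalid configuration or incompatible inputs (grid/mask mismatch, bad counts)."""


class DataError(CropCsiError):
    """Non-finite or structurally invalid data."""


class InsufficientDataError(DataError):
    """A series is too short for the requested operation."""


class DegenerateSeriesError(CropCsiError):
    """A series has zero variance where variability is required (e.g. standardisation)."""


class ModelFailureError(CropCsiError):
    """No usable calibration could be produced for a country."""
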