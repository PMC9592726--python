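"""Exception hierarchy shared across the pipeline stages."""


class BoldHrfError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BoldHrfError, ValueError):
    """An argument violates a precondition (non-positive dt, bad factor, ...)."""


class InvalidDataError(BoldHrfError, ValueError):
    """Input data violates a contract (non-positive run mean, wrong units, ...)."""


class InsufficientDataError(BoldHrfError, ValueError):
    """A series is too short for the requested operation."""


class EmptyRoiError(BoldHrfError, ValueError):
    """An ROI mask selects no voxels."""


class NoPositivePeakError(BoldHrfError, ValueError):
    """A curve has no positive excursion; HRF parameters are undefined."""


class ConfigurationError(BoldHrfError, ValueError):
    """A configuration references unknown labels or inconsistent settings."""


class GridMismatchError(BoldHrfError, ValueError):
    """Curves live on incompatible time grids and no resampling was requested."""
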