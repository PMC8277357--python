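"""Exception hierarchy. Every error the engine raises derives from NFTrainError."""


class NFTrainError(Exception):
    """Base class for all package errors."""


class InsufficientSamplesError(NFTrainError):
    """Signal shorter than one analysis window."""


class InvalidSignalError(NFTrainError):
    """Non-finite samples in the input signal."""


class BandRangeError(NFTrainError):
    """Requested band lies (partly) outside [0, fs/2]."""


class DegenerateSpectrumError(NFTrainError):
    """Weighted feedback denominator below the spectral floor."""


class CalibrationError(NFTrainError):
    """Calibration not separable or too little calibration data."""


class NyquistError(NFTrainError):
    """Sampling rate too low for a requested oscillation band."""


class TrajectoryError(NFTrainError):
    """Attention trajectory empty, overlapping, or not contiguous."""


class CohortError(NFTrainError):
    """Cohort specification invalid (e.g. fewer than 2 subjects)."""


class GroupingError(NFTrainError):
    """Channel grouping references a channel missing from the montage."""


class EDFError(NFTrainError):
    """Malformed or unreadable EDF file."""


class ZeroVarianceError(NFTrainError):
    """Paired differences have zero variance but a nonzero mean."""


class ConfigError(NFTrainError):
    """Configuration fails schema validation (unknown key, bad value)."""
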