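"""Exception hierarchy for the grasping-pattern pipeline."""


class GraspidError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GraspidError, ValueError):
    """Invalid configuration value or parameter combination."""


class DegenerateGeometryError(GraspidError, ValueError):
    """Marker geometry does not define the requested quantity
    (collinear palm markers, coincident phalange markers, zero vectors)."""


class MissingDataError(GraspidError, ValueError):
    """A marker or channel has missing (NaN) frames; the trial is rejected."""


class InputTooShortError(GraspidError, ValueError):
    """Time series too short for the requested filter or resampling."""


class CalibrationError(GraspidError, ValueError):
    """Calibration recording cannot produce a usable voltage-to-force curve."""


class SegmentationError(GraspidError, ValueError):
    """Reach/grasp/release phase boundaries could not be detected."""


class DegenerateDataError(GraspidError, ValueError):
    """Dataset statistics are degenerate (e.g. zero pooled variance)."""


class MetadataError(GraspidError, KeyError):
    """Required per-subject metadata (e.g. hand size) is missing."""


class ValidationError(GraspidError, ValueError):
    """A trial file failed structural validation."""
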