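"""Exception hierarchy.

Every failure mode the public API promises is a subclass of
:class:`CervidCTError`, so callers can catch the package's errors without
swallowing genuine bugs.
"""


class CervidCTError(Exception):
    """Base class for all package errors."""


class FormatError(CervidCTError):
    """Input file violates the expected on-disk format."""


class ConfigurationError(CervidCTError):
    """Required configuration (e.g. voxel size) is missing or inconsistent."""


class ParameterError(CervidCTError, ValueError):
    """A function argument violates its precondition."""


class GeometryError(CervidCTError):
    """An ROI/VOI does not fit inside the image frame."""


class SegmentationError(CervidCTError):
    """The gray-level histogram does not support the two-peak threshold rule."""


class EvaluationError(CervidCTError):
    """A morphometric estimator cannot be evaluated on this input."""


class InputError(CervidCTError):
    """A prediction-time input row is incomplete or mislabelled."""


class PipelineError(CervidCTError):
    """The end-to-end run could not produce any usable sample."""
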