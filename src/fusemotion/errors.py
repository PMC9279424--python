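"""Exception hierarchy shared across the pipeline stages."""


class FusemotionError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FusemotionError):
    """A structure or table file could not be parsed."""


class EmptyStructureError(FusemotionError):
    """A parsed model contained no usable atoms."""


class SelectionError(FusemotionError):
    """A domain selection matched no atoms."""


class CorrespondenceError(FusemotionError):
    """No residue pairs could be established between two structures."""


class DegenerateGeometryError(FusemotionError):
    """Too few or collinear points for a rigid superposition."""


class SamplingError(FusemotionError):
    """Grid sampling too coarse for the requested resolution."""


class ParameterError(FusemotionError):
    """A stage parameter is outside its documented range."""


class UndefinedCorrelationError(FusemotionError):
    """Zero-variance image under the correlation mask."""


class InconsistentSignalsError(FusemotionError):
    """Detector signals admit no non-negative composition."""


class NoTransitionError(FusemotionError):
    """No qualifying unfolding transition in a melt curve."""
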