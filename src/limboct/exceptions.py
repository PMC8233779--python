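"""Exception hierarchy for limboct."""


class LimboctError(Exception):
    """Base class for all limboct errors."""


class PhantomSpecError(LimboctError, ValueError):
    """A phantom specification violates its invariants."""


class SegmentationError(LimboctError):
    """Layer segmentation failed (e.g. no detectable surface in most columns)."""


class DegenerateLayerError(LimboctError):
    """A layer region is empty (boundaries touch or cross)."""


class DegenerateHistogramError(LimboctError):
    """Automatic thresholding is impossible (constant image)."""


class RoiError(LimboctError):
    """ROI construction failed (collinear contour points or empty mask)."""


class SeparationError(LimboctError):
    """Complete separation: the logistic MLE does not exist."""


class ConvergenceError(LimboctError):
    """Iterative fit failed to converge within the iteration budget."""
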