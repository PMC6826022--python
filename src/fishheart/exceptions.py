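"""Exception hierarchy for the fishheart pipeline.

Every stage raises a subclass of :class:`FishheartError` so callers can
distinguish pipeline failures from programming errors; orchestrators attach
the failing stage's name when re-raising.
"""


class FishheartError(Exception):
    """Base class for all fishheart pipeline errors."""


class InvalidParameterError(FishheartError, ValueError):
    """A simulation or analysis parameter violates its invariants."""


class RenderingError(FishheartError):
    """A synthetic object cannot be rendered inside the image bounds."""


class PackingError(FishheartError):
    """Synthetic objects cannot be placed without overlap."""


class SegmentationError(FishheartError):
    """No acceptable foreground component was found in a frame."""


class EmptyMaskError(FishheartError):
    """A geometry operation received an empty mask."""


class CycleDetectionError(FishheartError):
    """Cardiac cycle detection found an implausible number of cycles."""


class InsufficientFramesError(FishheartError):
    """Not enough frames to compute a strain/velocity series."""


class OpenLoopError(FishheartError):
    """Velocity-strain loop endpoints do not close within tolerance."""


class LobeDetectionError(FishheartError):
    """Doppler inflow waveform does not show two lobes per cycle."""


class ZeroDivisionInputError(FishheartError, ZeroDivisionError):
    """A ratio index was requested with a zero denominator."""


class MarkError(FishheartError):
    """Force-trace protocol marks are missing or out of order."""


class FitFailureError(FishheartError):
    """A nonlinear fit failed to converge or produced a non-physical rate."""


class InsufficientRiseError(FishheartError):
    """Force window has too little dynamic range to fit a rise."""


class InsufficientPointsError(FishheartError):
    """Too few data points for the requested fit."""


class InsufficientContractionsError(FishheartError):
    """Rundown QC needs at least two contractions."""


class NonPositiveCSAError(FishheartError, ValueError):
    """Cross-sectional area must be positive to normalise tension."""


class EmptyROIError(FishheartError):
    """Region of interest contains no pixels."""


class NoNucleiError(FishheartError):
    """No nuclei detected in the total-stain channel."""


class NoCellsError(FishheartError):
    """No labelled cells present."""


class ZeroWeightError(FishheartError, ValueError):
    """Body weight must be positive."""


class ProtocolError(FishheartError):
    """Swim-trial record is inconsistent with the stated protocol."""


class SurvivalDataError(FishheartError):
    """Survival data cannot support the requested test."""


class InsufficientDataError(FishheartError):
    """Group comparison needs at least two groups with two values each."""


class ZeroVarianceError(FishheartError):
    """Pooled variance is zero while group means differ."""


class StageError(FishheartError):
    """Wraps an error from a pipeline stage, recording which stage failed."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
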