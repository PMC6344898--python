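"""Exception types raised across the pipeline.

Each stage raises a dedicated subclass so that pipeline drivers can abort
with the failing stage's name while preserving intermediate artifacts.
"""


class OligoquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OligoquantError, ValueError):
    """A specification or ground-truth parameter violates its invariant."""


class OverlappingNucleiError(InvalidParameterError):
    """Planted nuclei overlap beyond the configured tolerance; the scene's
    ground truth would be ill-posed."""


class InsufficientStandardsError(OligoquantError, ValueError):
    """Fewer calibration standards than required for an affine fit."""


class DegenerateCalibrationError(OligoquantError, ValueError):
    """Calibration fit produced a non-positive slope."""


class DegenerateHistogramError(OligoquantError, ValueError):
    """Image has too few distinct grey levels for three-class thresholding."""


class CorrectionUnderflowError(OligoquantError, ValueError):
    """Reference ROI fell to or below background; bleach correction undefined."""


class DegenerateBleachError(OligoquantError, ValueError):
    """No bleach depth (post-bleach offset >= prebleach level)."""


class UndefinedNormalizationError(OligoquantError, ValueError):
    """Autocorrelation of a zero-mean intensity trace is undefined."""


class FitFailureError(OligoquantError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PipelineStageError(OligoquantError, RuntimeError):
    """A pipeline stage failed; names the stage and preserved artifacts."""

    def __init__(self, stage: str, message: str, artifacts: list | None = None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.artifacts = artifacts or []
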