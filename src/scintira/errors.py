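"""Exception hierarchy for the scintira pipeline."""


class ScintiraError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ScintiraError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class RenderingError(ScintiraError):
    """Phantom rendering failed (e.g. a landmark falls outside its view)."""


class LocalizationError(ScintiraError):
    """ROI localization failed (e.g. atlas landmark outside the image)."""


class MeasurementError(ScintiraError):
    """Uptake measurement failed (e.g. non-positive reference region)."""


class AnalysisError(ScintiraError, ValueError):
    """A statistical routine received input it cannot analyze."""


class StageError(ScintiraError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
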