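"""Exception hierarchy for the fibrilsaxs pipeline."""


class FibrilSAXSError(Exception):
    """Base class for all fibrilsaxs errors."""


class ValidationError(FibrilSAXSError, ValueError):
    """Invalid argument or inconsistent inputs."""


class ConfigError(ValidationError):
    """Invalid or incomplete analysis configuration."""


class FormatError(FibrilSAXSError):
    """Unsupported image bit layout or channel structure."""


class GeometryError(FibrilSAXSError):
    """Degenerate geometry (e.g. collinear points passed to the circle fit)."""


class EmptyDataError(FibrilSAXSError):
    """No valid pixels/bins available for the requested reduction."""


class PeakNotFoundError(FibrilSAXSError):
    """No local maximum found inside the search window."""


class CompensationError(FibrilSAXSError):
    """Cylinder-transform division left no defined bins."""


class PipelineError(FibrilSAXSError):
    """A pipeline stage failed; carries the stage name and source file."""

    def __init__(self, stage: str, source: str, message: str):
        self.stage = stage
        self.source = source
        super().__init__(f"[{stage}] {source}: {message}")
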