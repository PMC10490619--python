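"""Exception hierarchy shared across the pipeline stages."""


class VigilanceError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(VigilanceError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(VigilanceError, ValueError):
    """The input is too short / too sparse for the requested operation."""


class DegenerateInputError(VigilanceError, ValueError):
    """Input with no variability (or otherwise degenerate) where variability is required."""


class DataError(VigilanceError, ValueError):
    """Malformed or corrupt signal data (non-finite samples, non-monotonic time...)."""


class FormatError(VigilanceError, ValueError):
    """A file does not follow the expected on-disk layout or misses required metadata."""


class StructuralError(VigilanceError, ValueError):
    """Dataset-level inconsistency, e.g. a subject without both sessions."""


class FoldError(VigilanceError, RuntimeError):
    """A cross-validation fold cannot be trained (e.g. single-class training set)."""


class StageError(VigilanceError, RuntimeError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str, session: str | None = None):
        self.stage = stage
        self.session = session
        tag = f"[{stage}]" + (f" session={session}" if session else "")
        super().__init__(f"{tag} {message}")
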