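"""Exception types raised across the toolkit."""


class HsibandError(Exception):
    """Base class for all toolkit-specific errors."""


class FormatError(HsibandError):
    """A file on disk does not match the declared format (shape/size/layout)."""


class MetadataError(HsibandError):
    """Required metadata (e.g. the wavelength axis) is absent from a file."""


class ValidationError(HsibandError, ValueError):
    """An in-memory object violates a type invariant (non-finite values, shape mismatch)."""


class TrainingError(HsibandError, RuntimeError):
    """Optimisation diverged (non-finite loss); carries the epoch index."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch} (non-finite loss)")
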