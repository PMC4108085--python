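"""Exception types raised across the MSCC pipeline."""


class MSCCError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MSCCError):
    """Invalid or inconsistent configuration (unknown keys, bad scenario, ragged index lengths ...)."""


class SizingError(ConfigurationError):
    """Requested features cannot be placed on a chromosome of the configured length."""


class PlacementError(MSCCError):
    """Could not place the requested number of non-overlapping eligible regions."""


class NormalizationError(MSCCError):
    """Spike-in counts missing or non-positive for a (sample, library) that needs a scale factor."""


class StageError(MSCCError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed" + (f": {message}" if message else ""))
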