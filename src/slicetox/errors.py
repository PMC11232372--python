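"""Exception types shared across the pipeline."""


class SlicetoxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SlicetoxError, ValueError):
    """A parameter is outside its documented range."""


class InputError(SlicetoxError, ValueError):
    """Input data violates a precondition (shape, emptiness, geometry)."""


class GenerationError(SlicetoxError, RuntimeError):
    """The synthetic generator could not satisfy the requested configuration."""


class FitError(SlicetoxError, RuntimeError):
    """A model fit could not be performed on the given data."""


class ConfigError(SlicetoxError, ValueError):
    """A run configuration failed validation; carries all offenses at once."""

    def __init__(self, offenses):
        self.offenses = list(offenses)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {o}" for o in self.offenses))
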