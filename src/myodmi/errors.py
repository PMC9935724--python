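"""Exception hierarchy shared across the package."""


class MyodmiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MyodmiError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(MyodmiError):
    """An in-memory object violates a documented invariant."""


class GenerationError(MyodmiError):
    """Synthetic data could not be generated from the requested configuration."""


class ConfigurationError(MyodmiError):
    """A configuration value is outside its supported range."""


class DegenerateModelError(MyodmiError):
    """The forward model is too ill-conditioned to invert (shells or
    diffusivities collapse compartments onto each other)."""
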