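"""Exception hierarchy shared across the package."""


class FetaldeskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FetaldeskError):
    """A file or value does not conform to the expected layout."""


class SamplingError(FetaldeskError):
    """A time grid is non-uniform, non-monotone, or inconsistent with fs."""


class ConfigError(FetaldeskError, ValueError):
    """An invalid configuration value."""


class SequencingError(FetaldeskError):
    """Monitor time stepped backwards."""
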