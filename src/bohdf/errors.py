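"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent with the data it is applied to
    (e.g. a band edge at or above the Nyquist frequency)."""


class UnsupportedFormatError(ValueError):
    """An unknown trial container format was requested."""


class BackendUnavailableError(RuntimeError):
    """A deep-feature backend cannot run because its runtime dependency
    (e.g. torch/torchvision weights) is not installed."""
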