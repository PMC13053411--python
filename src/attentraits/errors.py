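"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An experiment design, population, or run configuration is invalid."""


class AnalysisError(RuntimeError):
    """An analysis stage cannot produce a defined result."""
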