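"""Error taxonomy: bad data vs. bad configuration vs. failed generation."""


class TrialMatchError(Exception):
    """Base class for package errors."""


class InputError(TrialMatchError, ValueError):
    """Malformed or degenerate data passed to an operation."""


class ConfigurationError(TrialMatchError, ValueError):
    """Invalid model, loss or run configuration."""


class GenerationError(TrialMatchError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""
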