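"""Exception types shared across the pipeline."""


class SemgaitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SemgaitError, ValueError):
    """A configuration value is invalid or inconsistent (e.g. cutoff above Nyquist)."""


class DataError(SemgaitError, ValueError):
    """Input data violates a precondition (NaNs, wrong shape, degenerate signal)."""
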