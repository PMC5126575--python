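"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a plain failure.
"""


class MnphError(Exception):
    """Base class for package errors."""


class ConfigError(MnphError):
    """Invalid configuration, preset name, or physical parameter."""


class DataError(MnphError):
    """Malformed or inconsistent input data (traces, metadata tables)."""


class NoAggregationError(MnphError):
    """Raised when an attraction zone is requested in the weak-coupling
    regime (coupling parameter Γ ≤ 1), where no aggregation zone exists."""
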