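"""Exception hierarchy shared across the pipeline.

Each class maps to a CLI exit code so shell callers can distinguish
bad configuration from bad data from a broken stage dependency.
"""


class ConfigError(ValueError):
    """Invalid parameter or configuration value (CLI exit code 2)."""

    exit_code = 2


class DataError(ValueError):
    """Invalid data content: non-finite pixels, non-binary masks, NaN loss (exit code 3)."""

    exit_code = 3


class ShapeError(DataError):
    """Array dimensions violate an operation's contract."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing an upstream artifact (exit code 4)."""

    exit_code = 4
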