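"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
any other failure -> 4.
"""


class GaLiversegError(Exception):
    """Base class for all package errors."""


class ConfigError(GaLiversegError):
    """Invalid configuration (bad parameter values, inconsistent shapes)."""


class DataError(GaLiversegError):
    """Invalid or unreadable input data."""


class GenerationError(GaLiversegError):
    """Phantom generation could not satisfy its constraints."""
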