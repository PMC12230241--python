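"""Exception types shared across the package."""


class SdlError(Exception):
    """Base class for all package errors."""


class ConfigError(SdlError, ValueError):
    """Invalid configuration (bad fractions, rates, thresholds...)."""


class DataError(SdlError, ValueError):
    """Malformed or insufficient input data."""


class LibraryError(SdlError, ValueError):
    """Invalid guide library (duplicate or ragged spacers...)."""
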