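"""Exceptions shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 1.
"""


class VtamuaError(Exception):
    """Base class for package errors."""


class ConfigError(VtamuaError):
    """Invalid configuration (bad probabilities, bands, paths...)."""


class DataError(VtamuaError):
    """Inconsistent input data (negative latencies, missing reward times...)."""
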