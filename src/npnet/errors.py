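"""Exception types shared across the pipeline."""


class NpnetError(Exception):
    """Base class for all package errors."""


class ConfigError(NpnetError):
    """A configuration value is invalid or unsatisfiable."""


class DataError(NpnetError):
    """An input file or record violates the expected contract."""
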