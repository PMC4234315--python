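"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataValidationError -> 3.
"""


class ErploadError(Exception):
    """Base class for all package errors."""


class ConfigError(ErploadError):
    """Invalid configuration or parameters."""


class DataValidationError(ErploadError):
    """Input data violates a documented contract."""
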