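"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class GwhapError(Exception):
    """Base class for all package errors."""


class ConfigError(GwhapError):
    """Invalid or incomplete configuration."""


class DataError(GwhapError):
    """Input data violates a precondition (bad file, empty result, mismatch)."""
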