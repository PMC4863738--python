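"""Exception hierarchy; the CLI maps these onto exit codes."""


class UtrMotifError(Exception):
    """Base class for package errors."""


class ConfigError(UtrMotifError):
    """Invalid configuration or missing input path (CLI exit code 2)."""


class DataError(UtrMotifError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class UntestableError(UtrMotifError):
    """A requested statistic has no data in one of its strata (exit code 4)."""
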