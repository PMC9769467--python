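"""Exception hierarchy. CLI exit codes map onto these classes."""


class PufError(Exception):
    """Base class for all package errors."""


class ConfigError(PufError):
    """Invalid configuration (exit code 2)."""


class DataFormatError(PufError):
    """Malformed or inconsistent input data (exit code 3)."""


class DegenerateStatisticsError(PufError):
    """A statistic is undefined on the given data (exit code 4)."""
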