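"""Exception taxonomy shared across modules.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class NascentqError(Exception):
    """Base class for all package errors."""


class ConfigError(NascentqError):
    """Invalid user configuration: bad thresholds, confounded designs, ..."""


class DataError(NascentqError):
    """Problems with input data: unreadable files, malformed records, ..."""


class CacheVersionError(DataError):
    """A persisted count cache was written by an incompatible version.

    The library refuses to load it; the CLI responds by rebuilding the
    cache from the original alignments.
    """
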