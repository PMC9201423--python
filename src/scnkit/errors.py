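"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class ScnkitError(Exception):
    """Base class for all scnkit errors."""


class ConfigError(ScnkitError):
    """Invalid configuration: contradictory or out-of-range parameters."""


class DataError(ScnkitError):
    """Invalid or infeasible data: malformed tables, disconnected graphs, ..."""
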