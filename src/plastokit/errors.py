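"""Exception hierarchy."""


class PlastokitError(Exception):
    """Base class for all package errors."""


class ParameterError(PlastokitError, ValueError):
    """Invalid simulation or analysis parameter."""


class StructureError(PlastokitError):
    """Genome structure is malformed or cannot be partitioned."""


class FormatError(PlastokitError):
    """Malformed input file."""


class ConfigError(PlastokitError):
    """Invalid pipeline configuration."""


class OutgroupError(PlastokitError):
    """Outgroup does not form a clade in the unrooted tree."""


class UndefinedRatioError(PlastokitError):
    """Isoform ratio requested with zero classified spanning reads."""
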