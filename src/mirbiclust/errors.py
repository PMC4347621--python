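"""Exception hierarchy.

``MirbiclustError`` is the package base; the CLI maps :class:`ConfigError`
to exit code 1 and every other :class:`MirbiclustError` (data problems) to
exit code 2.
"""


class MirbiclustError(Exception):
    """Base class for all package errors."""


class FormatError(MirbiclustError, ValueError):
    """A file or table violates the expected on-disk format."""


class ConflictError(FormatError):
    """Contradictory records, e.g. one miRNA mapped to two families."""


class DataError(MirbiclustError, ValueError):
    """Semantically invalid data (negative counts, out-of-range scores ...)."""


class EmptyResultError(DataError):
    """An operation removed everything (e.g. all libraries below the read cut)."""


class DegenerateVectorError(DataError):
    """A score vector has zero standard deviation and cannot be z-scored."""


class ConfigError(MirbiclustError, ValueError):
    """Invalid run configuration or command usage."""
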