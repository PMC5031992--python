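"""Exception hierarchy shared across the package."""


class CnaPhyloError(Exception):
    """Base class for all package errors."""


class UsageError(CnaPhyloError):
    """Invalid arguments or preconditions violated by the caller."""


class FormatError(CnaPhyloError):
    """Malformed input data (bad SEG rows, overlapping segments, ...)."""


class EmptyResultError(CnaPhyloError):
    """An operation removed everything (e.g. all fragments filtered out)."""
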